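import numpy as np
import pandas as pd
import pytest

from dcisatlas.cna import (
    MultiRegionSegmentation,
    Segment,
    SegmentProfile,
)


def profiles_from_means(means_by_region: dict[str, list[float]], bins: list[int],
                        bin_size: int = 1000) -> list[SegmentProfile]:
    """Build shared-segmentation profiles from segment means and bin counts."""
    edges = np.concatenate([[0], np.cumsum(bins)]) * bin_size
    out = []
    for rid, means in means_by_region.items():
        segs = tuple(
            Segment("chr1", int(edges[i]), int(edges[i + 1]), float(m), int(bins[i]))
            for i, m in enumerate(means)
        )
        out.append(SegmentProfile(region_id=rid, segments=segs))
    return out


def segmentation_from_means(means_by_region, bins, gamma=40.0):
    return MultiRegionSegmentation(
        sample_id="toy",
        regions=tuple(profiles_from_means(means_by_region, bins)),
        gamma=gamma,
    )


def bin_frame(values, chromosome="chr1", bin_size=10):
    values = np.asarray(values, dtype=float)
    starts = np.arange(values.size) * bin_size
    return pd.DataFrame(
        {
            "chromosome": chromosome,
            "start": starts,
            "end": starts + bin_size,
            "log2_ratio": values,
        }
    )


@pytest.fixture(scope="session")
def table1():
    from dcisatlas.synthetic import load_table1_fixture

    return load_table1_fixture()
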