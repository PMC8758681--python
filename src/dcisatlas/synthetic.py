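"""Seeded generators planting known truth for every pipeline stage.

Three simulators emulate the statistical structure the analysis modules
assume, so each stage can be validated against a planted ground truth
without any external data:

* :func:`simulate_clonal_cna` — multi-region bin-level log2 copy ratios
  from a rooted clonal event tree.  Each branch carries copy-number
  events (genomic interval + direction); a region's noise-free bin value
  is the sum of the log2 shifts of all events on its root-to-leaf path,
  and Gaussian bin noise is added on top.  The default magnitude (0.8)
  clears the loss/gain character thresholds even with sigma = 0.1 noise.
* :func:`simulate_variant_table` — candidate variant records mixing
  germline (VAF near 0.5 or 1.0, population-database annotated), somatic
  (sub-0.5 VAF, clean quality metrics, unannotated) and artifact (low
  VAF, degraded quality metrics) classes, with truth labels.
* :func:`simulate_immune_cohort` — per-region immune cell densities drawn
  from three planted state archetypes (Active / Suppressed / Excluded)
  with multiplicative log-normal dispersion; Ki67+ and Ki67- components
  are drawn separately and totals are their sums, so the density
  additivity invariant holds by construction.

All generators are pure functions of their spec (including its seed):
identical specs give identical outputs.  :func:`load_table1_fixture`
returns the packaged 43-block cohort table.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cna import DiscretizationParams
from .cohort import CohortTable, parse_cohort_table
from .immune import FEATURES
from .variants import VariantRecord

__all__ = [
    "ClonalEvent",
    "ClonalTreeNode",
    "ClonalSimSpec",
    "VariantSimSpec",
    "ImmuneSimSpec",
    "simulate_clonal_cna",
    "simulate_variant_table",
    "simulate_immune_cohort",
    "default_clonal_spec",
    "load_table1_fixture",
    "TABLE1_SHA256",
]

# Checksum of the packaged cohort-table fixture; guards silent corruption.
TABLE1_SHA256 = "23322287c491c837bb40f7c523f511e4a972e212322256d33d60815b06a559b0"


# ---------------------------------------------------------------------------
# clonal copy-number simulator


@dataclass(frozen=True)
class ClonalEvent:
    """One copy-number event: a bin interval shifted up or down."""

    chromosome: str
    start_bin: int
    end_bin: int  # half-open in bin index space
    direction: int  # +1 gain, -1 loss

    def __post_init__(self) -> None:
        if self.end_bin <= self.start_bin:
            raise ValueError("event end_bin <= start_bin")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


@dataclass(frozen=True)
class ClonalTreeNode:
    """Node of the planted event tree; leaves name regions."""

    name: str
    events: tuple[ClonalEvent, ...] = ()
    children: tuple["ClonalTreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["ClonalTreeNode"]:
        if self.is_leaf:
            return [self]
        return [l for c in self.children for l in c.leaves()]


@dataclass(frozen=True)
class ClonalSimSpec:
    """Planted clonal history: event tree, bin grid, noise, magnitude."""

    tree: ClonalTreeNode
    bins_per_chromosome: Mapping[str, int]
    sigma: float = 0.1
    magnitude: float = 0.8
    bin_size: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be positive")

    @property
    def n_regions(self) -> int:
        return len(self.tree.leaves())


def _check_branch_events(node: ClonalTreeNode) -> None:
    by_chrom: dict[str, list[ClonalEvent]] = {}
    for ev in node.events:
        by_chrom.setdefault(ev.chromosome, []).append(ev)
    for evs in by_chrom.values():
        evs = sorted(evs, key=lambda e: e.start_bin)
        for prev, cur in itertools.pairwise(evs):
            if cur.start_bin < prev.end_bin:
                raise ValueError(
                    f"overlapping events on branch {node.name!r}: "
                    f"{prev} and {cur}"
                )
    for child in node.children:
        _check_branch_events(child)


def simulate_clonal_cna(
    spec: ClonalSimSpec,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Bin tables per region plus the planted truth.

    Returns ``(bin_tables, truth)`` where each bin table has columns
    chromosome/start/end/log2_ratio and ``truth`` holds the event tree,
    the per-region noise-free values, the planted clades (leaf-name sets
    of every internal branch), the per-branch events, and the expected
    character matrix under default discretization with gains enabled.
    """
    _check_branch_events(spec.tree)
    leaves = spec.tree.leaves()
    region_ids = [l.name for l in leaves]
    if len(set(region_ids)) != len(region_ids):
        raise ValueError("duplicate region names in event tree")

    chroms = list(spec.bins_per_chromosome)
    offsets = {}
    total_bins = 0
    for c in chroms:
        offsets[c] = total_bins
        total_bins += spec.bins_per_chromosome[c]

    def event_track(events: Sequence[ClonalEvent]) -> np.ndarray:
        track = np.zeros(total_bins)
        for ev in events:
            if ev.chromosome not in offsets:
                raise ValueError(f"event on unknown chromosome {ev.chromosome!r}")
            if ev.end_bin > spec.bins_per_chromosome[ev.chromosome]:
                raise ValueError(f"event {ev} extends past its chromosome")
            o = offsets[ev.chromosome]
            track[o + ev.start_bin : o + ev.end_bin] += ev.direction * spec.magnitude
        return track

    # accumulate events root -> leaf
    clean: dict[str, np.ndarray] = {}
    clades: set[frozenset[str]] = set()
    branch_events: dict[str, tuple[ClonalEvent, ...]] = {}

    def walk(node: ClonalTreeNode, inherited: np.ndarray) -> None:
        track = inherited + event_track(node.events)
        branch_events[node.name] = node.events
        if node.is_leaf:
            clean[node.name] = track
        else:
            names = frozenset(l.name for l in node.leaves())
            if 1 < len(names) < len(region_ids):
                clades.add(names)
            for c in node.children:
                walk(c, track)

    walk(spec.tree, np.zeros(total_bins))

    rng = np.random.default_rng(spec.seed)
    tables: dict[str, pd.DataFrame] = {}
    chrom_col = np.concatenate(
        [np.repeat(c, spec.bins_per_chromosome[c]) for c in chroms]
    )
    start_col = np.concatenate(
        [np.arange(spec.bins_per_chromosome[c]) * spec.bin_size for c in chroms]
    )
    for rid in region_ids:
        noisy = clean[rid] + rng.normal(0.0, spec.sigma, size=total_bins)
        tables[rid] = pd.DataFrame(
            {
                "chromosome": chrom_col,
                "start": start_col,
                "end": start_col + spec.bin_size,
                "log2_ratio": noisy,
            }
        )

    truth = {
        "tree": spec.tree,
        "clades": clades,
        "branch_events": branch_events,
        "clean_values": {rid: clean[rid].copy() for rid in region_ids},
        "character_matrix": _expected_character_matrix(spec, clean, chroms, offsets),
    }
    return tables, truth


def _expected_character_matrix(
    spec: ClonalSimSpec,
    clean: Mapping[str, np.ndarray],
    chroms: Sequence[str],
    offsets: Mapping[str, int],
) -> pd.DataFrame:
    """Characters of the noise-free profiles on their exact segmentation.

    Segments are maximal runs of constant multi-region value vectors per
    chromosome (the segmentation any exact change-point method recovers
    at sigma = 0); runs shorter than the default min_probes are dropped,
    matching :func:`dcisatlas.cna.discretize`.
    """
    params = DiscretizationParams(include_gains=True)
    region_ids = list(clean)
    values = np.vstack([clean[r] for r in region_ids])
    columns: list[str] = []
    data: list[list[float]] = [[] for _ in region_ids]
    for c in chroms:
        o = offsets[c]
        n = spec.bins_per_chromosome[c]
        v = values[:, o : o + n]
        change = np.any(v[:, 1:] != v[:, :-1], axis=0)
        edges = [0, *(np.flatnonzero(change) + 1), n]
        for a, b in itertools.pairwise(edges):
            if b - a < params.min_probes:
                continue
            start = a * spec.bin_size
            end = b * spec.bin_size
            columns.append(f"{c}:{start}-{end}")
            for i in range(len(region_ids)):
                data[i].append(params.code(float(v[i, a])))
    return pd.DataFrame(data, index=region_ids, columns=columns)


def default_clonal_spec(seed: int = 0, sigma: float = 0.1) -> ClonalSimSpec:
    """Canonical 4-region nested clonal history: ((A,B),(C,D)) below a trunk.

    Two chromosomes of 1400 bins, laid out in 200-bin event slots.  The
    trunk and both internal branches carry three events apiece and every
    region one private event.  A 200-bin slot at magnitude 0.8 is sized
    so that even a single-region (private) event repays the shared
    breakpoint penalty at the pipeline default gamma = 40: removing one
    of its breakpoints would raise the fit error by roughly
    (200*200/400) * 0.8^2 = 64 > 40.
    """
    E = ClonalEvent
    s = 200  # slot width in bins

    def slot(chrom: str, i: int, direction: int) -> ClonalEvent:
        return E(chrom, i * s, (i + 1) * s, direction)

    tree = ClonalTreeNode(
        name="trunk",
        events=(slot("chr1", 0, -1), slot("chr1", 1, +1), slot("chr2", 0, -1)),
        children=(
            ClonalTreeNode(
                name="AB",
                events=(slot("chr1", 2, -1), slot("chr1", 3, +1), slot("chr2", 1, -1)),
                children=(
                    ClonalTreeNode("A", events=(slot("chr1", 4, -1),)),
                    ClonalTreeNode("B", events=(slot("chr2", 2, +1),)),
                ),
            ),
            ClonalTreeNode(
                name="CD",
                events=(slot("chr1", 5, -1), slot("chr2", 3, +1), slot("chr2", 4, -1)),
                children=(
                    ClonalTreeNode("C", events=(slot("chr1", 6, -1),)),
                    ClonalTreeNode("D", events=(slot("chr2", 5, +1),)),
                ),
            ),
        ),
    )
    return ClonalSimSpec(
        tree=tree,
        bins_per_chromosome={"chr1": 7 * s, "chr2": 7 * s},
        sigma=sigma,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# variant-table simulator


@dataclass(frozen=True)
class VariantSimSpec:
    """Counts and distributions of planted variant classes.

    Defaults reflect a tumor-only exome: residual germline records
    dominate the candidate list, with a smaller somatic fraction
    (VAF uniform on 0.1-0.4) and sequencing artifacts carrying degraded
    quality metrics.
    """

    n_germline: int = 120
    n_somatic: int = 40
    n_artifact: int = 40
    hom_fraction: float = 0.3  # germline records near VAF 1.0 vs 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_germline, self.n_somatic, self.n_artifact) < 0:
            raise ValueError("class counts must be >= 0")


_BASES = np.array(list("ACGT"))


def _good_quality(rng: np.random.Generator, rec_kwargs: dict) -> dict:
    rec_kwargs.update(
        depth=int(rng.integers(40, 400)),
        mapping_quality=float(rng.uniform(50, 60)),
        mean_read_position=float(rng.uniform(25, 45)),
        mean_mismatches=float(rng.uniform(0.2, 1.8)),
        microsatellite_length=int(rng.integers(0, 3)),
        tlod=float(rng.uniform(15, 80)),
        fs_phred=float(rng.uniform(0, 6)),
    )
    return rec_kwargs


def simulate_variant_table(
    spec: VariantSimSpec,
) -> tuple[list[VariantRecord], list[str]]:
    """Variant records plus parallel truth labels.

    Labels are ``somatic``, ``germline`` and ``artifact``.  Germline
    records carry heterozygous (~0.5) or homozygous (~1.0) VAFs and
    population-database annotations above the common-variant cutoffs;
    somatic records have clean metrics and no population annotation;
    artifacts combine sub-threshold VAF with one or more degraded quality
    metrics.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[VariantRecord] = []
    labels: list[str] = []

    def base_site() -> dict:
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        return dict(
            chromosome=f"chr{int(rng.integers(1, 23))}",
            position=int(rng.integers(1, 200_000_000)),
            ref=str(ref),
            alt=str(alt),
            gene=f"GENE{int(rng.integers(1, 400))}",
        )

    for _ in range(spec.n_germline):
        kw = _good_quality(rng, base_site())
        if rng.uniform() < spec.hom_fraction:
            vaf = float(np.clip(rng.normal(0.97, 0.02), 0.0, 1.0))
        else:
            vaf = float(np.clip(rng.normal(0.5, 0.04), 0.0, 1.0))
        kw.update(
            vaf=vaf,
            population_af=float(10 ** rng.uniform(-2.6, -0.4)),
            population_count=int(rng.integers(20, 5000)),
        )
        records.append(VariantRecord(**kw))
        labels.append("germline")

    for _ in range(spec.n_somatic):
        kw = _good_quality(rng, base_site())
        kw.update(vaf=float(rng.uniform(0.11, 0.4)))
        records.append(VariantRecord(**kw))
        labels.append("somatic")

    for _ in range(spec.n_artifact):
        kw = _good_quality(rng, base_site())
        kw.update(vaf=float(rng.uniform(0.02, 0.095)))
        # degrade 1-3 additional quality metrics
        degradations = rng.choice(5, size=int(rng.integers(1, 4)), replace=False)
        if 0 in degradations:
            kw["mapping_quality"] = float(rng.uniform(20, 44))
        if 1 in degradations:
            kw["mean_read_position"] = float(rng.uniform(2, 12))
        if 2 in degradations:
            kw["mean_mismatches"] = float(rng.uniform(3, 6))
        if 3 in degradations:
            kw["tlod"] = float(rng.uniform(0, 8))
        if 4 in degradations:
            kw["fs_phred"] = float(rng.uniform(15, 40))
        records.append(VariantRecord(**kw))
        labels.append("artifact")

    return records, labels


# ---------------------------------------------------------------------------
# immune-cohort simulator

# Archetype densities (cells/mm^2): (Ki67+ , Ki67-) per cell type and
# compartment.  Values echo the magnitudes seen in compartmentalized
# DCIS immunoprofiling: lymphocytes concentrate in stroma everywhere;
# the Active state keeps a strong epithelial T-cell presence, the
# Suppressed state trades T-cells for B-cells and T-regs, and the
# Excluded state confines lymphocytes almost entirely to stroma.
_ARCHETYPES: dict[str, dict[str, tuple[float, float]]] = {
    "Active": {
        "TC_Epi": (30.0, 90.0),
        "TC_Str": (90.0, 310.0),
        "BC_Epi": (1.0, 3.0),
        "BC_Str": (8.0, 32.0),
        "TREG_Epi": (1.0, 3.0),
        "TREG_Str": (6.0, 24.0),
    },
    "Suppressed": {
        "TC_Epi": (1.5, 13.5),
        "TC_Str": (8.0, 72.0),
        "BC_Epi": (0.8, 7.2),
        "BC_Str": (9.0, 81.0),
        "TREG_Epi": (1.0, 9.4),
        "TREG_Str": (6.0, 54.0),
    },
    "Excluded": {
        "TC_Epi": (0.5, 4.5),
        "TC_Str": (70.0, 280.0),
        "BC_Epi": (0.05, 0.45),
        "BC_Str": (12.0, 48.0),
        "TREG_Epi": (0.05, 0.45),
        "TREG_Str": (10.0, 40.0),
    },
}


@dataclass(frozen=True)
class ImmuneSimSpec:
    """Planted immune cohort: regions per state and dispersion."""

    regions_per_state: int = 10
    dispersion: float = 0.3  # sigma of multiplicative log-normal noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regions_per_state < 2:
            raise ValueError("need at least 2 regions per state")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def simulate_immune_cohort(
    spec: ImmuneSimSpec,
) -> tuple[pd.DataFrame, pd.Series]:
    """(regions x 18 density matrix, truth immune state per region)."""
    rng = np.random.default_rng(spec.seed)
    rows = {}
    truth = {}
    for state, arch in _ARCHETYPES.items():
        for i in range(spec.regions_per_state):
            rid = f"{state[:3].upper()}_{i:02d}"
            densities = {}
            for ct in ("BC", "TC", "TREG"):
                for comp in ("Epi", "Str"):
                    p_mean, np_mean = arch[f"{ct}_{comp}"]
                    noise_p = rng.lognormal(0.0, spec.dispersion) if spec.dispersion else 1.0
                    noise_np = rng.lognormal(0.0, spec.dispersion) if spec.dispersion else 1.0
                    p = p_mean * noise_p
                    np_ = np_mean * noise_np
                    densities[f"{ct}_p_{comp}"] = p
                    densities[f"{ct}_np_{comp}"] = np_
                    densities[f"{ct}_t_{comp}"] = p + np_
            rows[rid] = [densities[f] for f in FEATURES]
            truth[rid] = state
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURES))
    return matrix, pd.Series(truth, name="immune_state")


# ---------------------------------------------------------------------------
# packaged fixture


def load_table1_fixture() -> CohortTable:
    """Load the packaged 43-block cohort table (checksum-guarded)."""
    text = (
        resources.files("dcisatlas").joinpath("data/table1.tsv").read_text(encoding="utf-8")
    )
    digest = hashlib.sha256(text.encode("utf-8")).hexdigest()
    if digest != TABLE1_SHA256:
        raise RuntimeError(
            f"cohort fixture is corrupted (sha256 {digest} != {TABLE1_SHA256})"
        )
    return parse_cohort_table(text)
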