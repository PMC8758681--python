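Patient ID	Block ID	Age at Index	Size (cm)	Laterality	Grade	Architecture	ER	HER2	N. of Regions	Diagnosis Order
MCL76_044	12800	56	0.9	Left	Low	Cribriform	+	-	1	Index
MCL76_049	18100	50	6	Left	Low	Cribriform	+	-	1	Index
MCL76_060	16100	47	17	Left	Low	Cribriform	+	-	3	Index
MCL76_061	16200	34	8	Left	Low	Cribriform	+	-	4	Index
MCL76_064	15200	78	0.4	Left	Low	Cribriform	+	-	3	Recur. (+18 mos.)
MCL76_066	14400	70	1.1	Right	Low	Cribriform	+	-	3	Index
MCL76_066	16500	70	0.3	Right	Low	ADH	+	-	1	Recur. (+14 mos.)
MCL76_076	15700	45	4.1	Right	Low	Cribriform	+	-	5	Index
MCL76_078	15500	68	1.4	Left	Low	Solid	+	-	3	Index
MCL76_080	15800	59	3.7	Left	Low	ADH	+	-	3	Index
MCL78_020	10001	59	0.3	Right	Low	Cribriform	+	+	1	Index
MCL76_012	11600	50	3.6	Right	Inter.	Solid	+	-	2	Index
MCL76_048	13100	51	3.8	Right	Inter.	Cribriform	+	-	3	Index
MCL76_064	14600	78	NA	Left	Inter.	Solid	+	NA	1	Index
MCL76_067	16600	54	6	Left	Inter.	Solid	+	+	3	Index
MCL76_070	16400	69	8	Right	Inter.	Solid	+	-	3	Index
MCL76_071	14800	68	5.8	Right	Inter.	Micropapillary	-	-	3	Index
MCL76_074	14700	45	14	Right	Inter.	Cribriform	+	-	3	Index
MCL76_077	15300	70	1.2	Left	Inter.	Cribriform	-	+	2	Index
MCL76_079	15400	62	3.4	Right	Inter.	Cribriform	-	+	3	Index
MCL78_001	10001	50	2.5	Right	Inter.	Cribriform	NA	-	1	Index
MCL78_002	10001	48	2	Left	Inter.	Solid	+	-	1	Index
MCL78_006	10001	75	4	Left	Inter.	Cribriform	+	+	1	Index
MCL78_007	10001	43	1.6	Right	Inter.	Cribriform	+	+	1	Index
MCL78_008	10001	66	1.5	Right	Inter.	Solid	+	+	1	Index
MCL78_009	10001	78	2.4	Right	Inter.	Solid	+	-	1	Index
MCL78_010	10001	67	1.1	Left	Inter.	Cribriform	-	+	1	Index
MCL78_011	10001	59	0.6	Right	Inter.	Solid	+	+	1	Index
MCL78_013	10001	63	2.2	Right	Inter.	Mixed	-	+	1	Index
MCL78_016	10001	65	4.5	Left	Inter.	Solid	-	+	1	Index
MCL78_017	10001	52	2.5	Left	Inter.	Solid	+	+	1	Index
MCL78_018	10001	65	2	Right	Inter.	Mixed	+	equ	2	Index
MCL76_007	11000	78	3.5	Left	High	Solid	-	-	3	Index
MCL76_007	11100	78	2.6	Right	High	Solid	-	-	4	Recur. (+39 mos.)
MCL76_016	11800	35	5	Left	High	Mixed	+	+	4	Index
MCL76_025	16800	75	1.2	Right	High	Solid	-	NA	2	Index
MCL76_068	14900	59	9.5	Left	High	Cribriform	-	+	3	Index
MCL78_003	10001	43	5	Left	High	Solid	+	equ	1	Index
MCL78_005	10001	81	0.5	Right	High	Solid	+	-	1	Index
MCL78_012	10001	54	4	Right	High	Solid	-	+	1	Index
MCL78_012	10014	54	3	Right	High	Solid	-	NA	1	Synchronous
MCL78_015	10001	57	0.5	Left	High	Micropapillary	+	+	1	Index
MCL78_019	10001	57	1.9	Left	High	Solid	-	equ	1	Index
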