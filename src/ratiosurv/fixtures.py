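"""Packaged in-study fixture tables.

``rfs_screen_fixture`` returns the published relapse-free-survival screen of
the top TNBC-vs-LumA differentially expressed genes on the two sides of
the anticorrelated module pair (M2 numerator side, M12 denominator side),
with kME, DEG FDR, log2 difference, Kaplan-Meier log-rank p, direction
code, probe availability and the one alternate-platform override (OPRK1,
array log-rank p = 5.6e-4).

``round2_recipe`` returns the round-2 candidate-pool source lists.  Gene
symbols that were published are used verbatim; the remaining entries of
the ranked-DEG source tables were never published, so SYNTHETIC
placeholder symbols (e.g. ``M11DEG04``) stand in for them — pool sizes and
assembly mechanics are unaffected.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

_RFS_SCREEN = """\
gene	side	kme	fdr	log2diff	logrank_p	direction	probe	selected
TFF1	M2	0.55	7.13e-52	-8.18	0.011	+	1	1
AGR3	M2	0.61	9.16e-86	-7.61	0.0056	+	0	0
TFF3	M2	0.56	2.87e-70	-7.14	0.034	+	1	0
SRARP	M2	0.54	1.11e-47	-6.88	NA	NA	1	0
AGR2	M2	0.60	2.63e-71	-6.73	0.014	+	1	1
ESR1	M2	0.83	6.05e-93	-6.38	0.01	+	1	0
GP2	M2	0.48	6.38e-34	-5.94	0.0061	+	1	1
CT62	M2	0.69	6.94e-85	-5.92	0.0062	+	0	0
LINC00504	M2	0.74	3.06e-98	-5.79	NA	NA	1	0
FOXA1	M2	0.47	1.59e-90	-5.75	0.091	ns	1	0
POTEKP	M2	0.66	8.69e-46	-5.70	NA	NA	1	0
ENSG00000240800	M2	0.53	4.35e-33	-5.62	NA	NA	1	0
ABCC8	M2	0.71	4.47e-49	-5.51	0.00056	+	1	1
ENSG00000235584	M2	0.62	2.03e-33	-5.50	NA	NA	1	0
TNRC18P1	M2	0.67	3.82e-59	-5.50	NA	NA	1	0
SLC44A4	M2	0.40	1.92e-71	-5.50	0.017	+	1	0
ERBB4	M2	0.70	2.00e-68	-5.47	0.008	+	1	1
SCUBE2	M2	0.75	1.09e-65	-5.47	0.00045	+	1	1
TTC6	M2	0.62	1.63e-75	-5.43	4.30e-05	+	0	0
LINC02568	M2	0.65	3.90e-61	-5.28	NA	NA	1	0
HORMAD1	M12	0.54	2.46e-61	6.35	0.4	ns	1	0
ART3	M12	0.67	4.74e-64	6.19	0.0035	-	1	1
LINC01956	M12	0.64	5.79e-55	5.59	NA	NA	1	0
FOXCUT	M12	0.78	9.44e-67	5.50	NA	NA	1	0
GABBR2	M12	0.63	4.14e-42	5.23	0.069	ns	1	0
ZIC1	M12	0.52	2.77e-37	4.99	0.097	ns	1	0
NKX1-2	M12	0.75	1.06e-38	4.88	NA	NA	1	0
PRSS33	M12	0.57	2.54e-23	4.68	0.0035	-	0	0
ENSG00000179066	M12	0.60	5.26e-55	4.38	NA	NA	1	0
ENSG00000248538	M12	0.63	3.82e-35	4.38	NA	NA	1	0
GFRA3	M12	0.52	1.33e-44	4.31	0.22	ns	1	0
NDUFB4P11	M12	0.70	1.12e-40	4.24	NA	NA	1	0
SLC26A9	M12	0.65	6.60e-39	4.12	0.061	ns	1	0
FZD9	M12	0.64	5.05e-61	4.11	0.0027	-	1	1
PSAT1	M12	0.81	2.39e-59	4.09	0.0042	-	1	1
CASC8	M12	0.64	4.83e-49	4.09	NA	NA	1	0
LINC01198	M12	0.68	4.54e-28	4.09	0.29	ns	1	0
OPRK1	M12	0.60	1.45e-27	3.95	0.35	ns	1	1
ABCA13	M12	0.57	3.08e-29	3.82	0.3	ns	1	0
MARCO	M12	0.64	8.72e-34	3.81	0.011	-	1	1
YBX1	M12	0.73	3.18e-53	1.42	0.12	ns	1	0
"""

#: the published alternate-platform override for OPRK1 (array data)
OPRK1_ARRAY_P = 0.00056

#: genes excluded from nomination as established disease drivers
KNOWN_DRIVERS = frozenset({"ESR1"})


def rfs_screen_fixture() -> pd.DataFrame:
    """The packaged single-gene RFS screen rows (both module sides)."""
    df = pd.read_csv(io.StringIO(_RFS_SCREEN), sep="\t", na_values=["NA"])
    df["probe"] = df["probe"].astype(bool)
    df["selected"] = df["selected"].astype(bool)
    df["override_p"] = np.where(df["gene"] == "OPRK1", OPRK1_ARRAY_P, np.nan)
    return df


def _placeholders(prefix: str, n: int, known: list[str]) -> list[str]:
    """Known published symbols first, SYNTHETIC placeholders for the rest."""
    fill = [f"{prefix}{i:02d}" for i in range(1, n - len(known) + 1)]
    return known + fill


def round2_recipe() -> tuple[dict, dict]:
    """Round-2 candidate pool sources, keyed by provenance.

    Numerator side (M2-like, 24 genes): top 14 M11 DEGs, top 5 M19 DEGs
    plus NCAM2, the two round-1 carryovers ERBB4 and SCUBE2, and the two
    interaction-implicated DEGs AHNAK (M5) and VAV3 (M2).  Denominator side
    (M12-like, 34 genes): the bottleneck CEBPB (M12), negative control
    CEBPG (M7), the M12-hub interaction DEGs CDCA7/CTPS1/MCM7, the three
    round-1 carryovers ART3/FZD9/PSAT1, the top 12 M8 DEGs and the top 14
    M21 DEGs.  Unpublished ranked-DEG entries are SYNTHETIC placeholders.
    """
    numerator = {
        "M11_top_degs": _placeholders("M11DEG", 14,
                                      ["BIK", "GPRC5C", "SPTLC2"]),
        "M19_top_degs": _placeholders("M19DEG", 5, []),
        "M19_lower_ranked": ["NCAM2"],
        "round1_carryover": ["ERBB4", "SCUBE2"],
        "interaction_degs": ["AHNAK", "VAV3"],
    }
    denominator = {
        "bottleneck": ["CEBPB"],
        "negative_control": ["CEBPG"],
        "m12_hub_interactors": ["CDCA7", "CTPS1", "MCM7"],
        "round1_carryover": ["ART3", "FZD9", "PSAT1"],
        "M8_top_degs": _placeholders("M8DEG", 12, ["TPO"]),
        "M21_top_degs": _placeholders("M21DEG", 14, ["DUSP4"]),
    }
    return numerator, denominator
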