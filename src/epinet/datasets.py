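"""Small bundled reference tables.

``double_mutant_epistasis()`` returns the published epistatic-deviation
estimates (epsilon on the relative-fitness scale, with assay-level
variances and per-pair p-values) for the eight engineered rho + rpoB
double mutants of E. coli REL1206 at three assay temperatures.  These
printed estimates are the canonical worked-example input for the pooled
epistasis statistics and the cross-environment ANOVA.

``module_summary()`` returns the published per-module gene counts of the
signed coexpression network built from the same study system: total genes,
genes with significant expression epistasis, hub genes, and hub genes with
significant epistasis, per color-named module.
"""

from __future__ import annotations

import pandas as pd

_EPSILON_ROWS = [
    # double_id, eps42, var42, p42, eps37, var37, p37, eps20, var20, p20
    ("rhoA43T+rpoBI572F", -0.2325, 0.0182, 0.000, -0.0319, 0.0033, 0.116, -0.0283, 0.0020, 0.0508),
    ("rhoA43T+rpoBI572L", -0.2680, 0.0418, 0.0043, -0.0171, 0.0031, 0.383, -0.0468, 0.0023, 0.0188),
    ("rhoT231A+rpoBI572F", -0.2430, 0.0218, 0.0001, -0.0430, 0.0034, 0.036, -0.0024, 0.0053, 0.9194),
    ("rhoT231A+rpoBI572L", -0.1802, 0.0505, 0.0180, -0.0155, 0.0034, 0.401, 0.0377, 0.0045, 0.0772),
    ("rhoI15F+rpoBI572F", -0.0370, 0.0215, 0.4431, -0.0304, 0.0045, 0.146, -0.0425, 0.0045, 0.0509),
    ("rhoI15F+rpoBI572L", -0.0010, 0.0318, 0.9866, -0.0224, 0.0033, 0.281, 0.0078, 0.0037, 0.7137),
    ("rhoI15N+rpoBI572F", -0.0635, 0.02874, 0.2938, -0.0318, 0.0027, 0.073, 0.0184, 0.0029, 0.2600),
    ("rhoI15N+rpoBI572L", -0.0446, 0.0430, 0.5898, -0.0360, 0.0014, 0.020, -0.0118, 0.0018, 0.4721),
]

_MODULE_ROWS = [
    # module, n_genes, n_epistatic, n_hubs, n_epistatic_hubs
    ("turquoise", 1534, 184, 152, 46),
    ("blue", 919, 49, 92, 12),
    ("brown", 373, 12, 37, 1),
    ("green", 260, 80, 26, 20),
    ("black", 160, 18, 16, 11),
    ("red", 248, 2, 25, 0),
    ("yellow", 350, 61, 35, 27),
]


def double_mutant_epistasis() -> pd.DataFrame:
    """Published per-pair epsilon estimates in long format.

    Columns: double_id, temperature (degC), epsilon, var_assay, p.
    """
    rows = []
    for (did, e42, v42, p42, e37, v37, p37, e20, v20, p20) in _EPSILON_ROWS:
        rows.append((did, 42.2, e42, v42, p42))
        rows.append((did, 37.0, e37, v37, p37))
        rows.append((did, 20.0, e20, v20, p20))
    return pd.DataFrame(rows, columns=["double_id", "temperature", "epsilon",
                                       "var_assay", "p"])


def module_summary() -> pd.DataFrame:
    """Published per-module gene/hub counts with derived percentage columns."""
    df = pd.DataFrame(_MODULE_ROWS, columns=["module", "n_genes", "n_epistatic",
                                             "n_hubs", "n_epistatic_hubs"])
    df["pct_epistatic"] = 100.0 * df["n_epistatic"] / df["n_genes"]
    df["pct_epistatic_hubs"] = 100.0 * df["n_epistatic_hubs"] / df["n_hubs"]
    return df
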