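"""Efficiency-corrected relative qPCR quantification.

The amplification factor derives from the slope of the standard-curve
regression of Ct on log10 dilution (E = 10^(-1/slope); a perfect doubling
chemistry gives slope ~ -3.3219 and E ~ 2), and the expression ratio is
E_goi^dCt_goi / E_ref^dCt_ref with dCt = Ct(control) - Ct(treated), so a
ratio above 1 means up-regulation in the treated condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from regconverge.errors import InputError


def amplification_factor(slope: float) -> float:
    """E = 10^(-1/slope); slope must be nonzero (typically negative)."""
    if slope == 0:
        raise InputError("slope must be nonzero")
    return float(10.0 ** (-1.0 / slope))


def efficiency_percent(E: float) -> float:
    """Efficiency as a percentage: (E - 1) * 100; E=2 (perfect doubling) -> 100%."""
    if E <= 1:
        raise InputError("amplification factor must exceed 1")
    return (E - 1.0) * 100.0


def pfaffl_ratio(E_goi: float, dCt_goi: float, E_ref: float, dCt_ref: float) -> float:
    """Pfaffl expression ratio: E_goi^dCt_goi / E_ref^dCt_ref."""
    if E_goi <= 1 or E_ref <= 1:
        raise InputError("amplification factors must exceed 1")
    return float(E_goi**dCt_goi / E_ref**dCt_ref)


def standard_curve_slope(log10_dilution, ct) -> float:
    """Least-squares slope of Ct versus log10 dilution."""
    x = np.asarray(log10_dilution, dtype=float)
    y = np.asarray(ct, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise InputError("need >=2 paired (dilution, Ct) points")
    return float(np.polyfit(x, y, 1)[0])


def pfaffl_table(
    efficiencies: pd.Series,
    ct: pd.DataFrame,
    reference_gene: str,
    control_sample: str,
    treated_sample: str,
) -> pd.DataFrame:
    """Per-gene Pfaffl ratios for one contrast.

    ``efficiencies``: gene -> E. ``ct``: genes x samples Ct values.
    dCt = Ct(control) - Ct(treated) for every gene including the reference.
    """
    if reference_gene not in ct.index:
        raise InputError(f"reference gene {reference_gene!r} missing from Ct table")
    for s in (control_sample, treated_sample):
        if s not in ct.columns:
            raise InputError(f"sample {s!r} missing from Ct table")
    e_ref = float(efficiencies[reference_gene])
    dct_ref = float(ct.loc[reference_gene, control_sample] - ct.loc[reference_gene, treated_sample])
    rows = []
    for g in ct.index:
        if g == reference_gene:
            continue
        dct = float(ct.loc[g, control_sample] - ct.loc[g, treated_sample])
        rows.append(
            {
                "gene_id": g,
                "E": float(efficiencies[g]),
                "dCt": dct,
                "ratio": pfaffl_ratio(float(efficiencies[g]), dct, e_ref, dct_ref),
            }
        )
    return pd.DataFrame(rows)
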