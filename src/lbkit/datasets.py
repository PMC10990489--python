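"""Reference best-fit parameters bundled with the package.

These are the published best-fit (EC50, Etop) pairs, with standard errors,
for FGF4, FGF8 and FGF9 acting on FGFR1c across seven readouts: receptor
phosphorylation at Y653/654 and Y766, PLCgamma and FRS2 phosphorylation,
receptor downregulation, and two chondrocyte responses (growth arrest and
collagen type 2 loss).  They serve as ready-made inputs to the bias module,
so the full bias map can be recomputed without any raw gel data.

The bias map pins, for every (response pair, ligand) combination, which
response is the numerator of the activity ratio.  The published coefficient
magnitudes are reproduced with numerator = second-listed response for the
phosphorylation/downregulation pairs and numerator = first-listed response
for the collagen-loss/growth-arrest pair; the API never infers ordering
from labels.
"""

from __future__ import annotations

import pandas as pd

from .dose_response import HillFit

__all__ = [
    "REFERENCE_LIGAND",
    "reference_fit_table",
    "reference_hill_fit",
    "reference_bias_map",
]

REFERENCE_LIGAND = "FGF8"

# response, ligand, EC50 (M), se, Etop, se
_FITS = [
    ("pY653/4", "FGF4", 4.77e-10, 0.42e-10, 0.95, 0.03),
    ("pY653/4", "FGF8", 1.04e-8, 0.23e-8, 1.11, 0.07),
    ("pY653/4", "FGF9", 2.09e-9, 0.31e-9, 0.70, 0.02),
    ("PLCg", "FGF4", 7.98e-11, 2.15e-11, 0.80, 0.04),
    ("PLCg", "FGF8", 1.05e-9, 0.23e-9, 0.99, 0.03),
    ("PLCg", "FGF9", 2.05e-10, 0.40e-10, 0.62, 0.02),
    ("pY766", "FGF4", 5.84e-10, 1.26e-10, 0.76, 0.05),
    ("pY766", "FGF8", 1.42e-8, 0.25e-8, 1.16, 0.07),
    ("pY766", "FGF9", 1.94e-9, 0.71e-9, 0.56, 0.05),
    ("pFRS2", "FGF4", 3.42e-10, 0.70e-10, 0.94, 0.06),
    ("pFRS2", "FGF8", 1.62e-9, 0.29e-9, 0.98, 0.03),
    ("pFRS2", "FGF9", 1.65e-9, 0.15e-9, 0.52, 0.01),
    ("downregulation", "FGF4", 7.34e-10, 4.54e-10, 0.27, 0.04),
    ("downregulation", "FGF8", 1.39e-8, 0.39e-8, 0.63, 0.05),
    ("downregulation", "FGF9", 6.80e-9, 2.08e-9, 0.42, 0.02),
    ("growth arrest", "FGF4", 2.59e-12, 1.1e-13, 0.99, 0.004),
    ("growth arrest", "FGF8", 1.60e-9, 2.3e-10, 1.14, 0.04),
    ("growth arrest", "FGF9", 5.89e-11, 8.5e-12, 0.95, 0.004),
    ("collagen2 loss", "FGF4", 1.24e-11, 2.79e-12, 1.02, 0.01),
    ("collagen2 loss", "FGF8", 8.51e-11, 2.86e-11, 0.77, 0.03),
    ("collagen2 loss", "FGF9", 5.67e-11, 2.89e-11, 0.86, 0.06),
]

# (label, response_num, response_den) for every published response pair
_BIAS_PAIRS = [
    ("pY653/4 vs pY766", "pY766", "pY653/4"),
    ("pY653/4 vs PLCg", "PLCg", "pY653/4"),
    ("pY653/4 vs pFRS2", "pFRS2", "pY653/4"),
    ("pY766 vs PLCg", "PLCg", "pY766"),
    ("pY766 vs pFRS2", "pFRS2", "pY766"),
    ("PLCg vs pFRS2", "pFRS2", "PLCg"),
    ("pY653/4 vs downregulation", "downregulation", "pY653/4"),
    ("pY766 vs downregulation", "downregulation", "pY766"),
    ("PLCg vs downregulation", "downregulation", "PLCg"),
    ("pFRS2 vs downregulation", "downregulation", "pFRS2"),
    ("collagen2 loss vs growth arrest", "collagen2 loss", "growth arrest"),
]


def reference_fit_table() -> pd.DataFrame:
    """Bundled (EC50, Etop) fit table in the dose_response fits CSV layout."""
    return pd.DataFrame(
        _FITS, columns=["response_name", "ligand", "ec50_M", "se_ec50_M", "etop", "se_etop"]
    )


def reference_hill_fit(response: str, ligand: str) -> HillFit:
    """One bundled fit as a :class:`~lbkit.dose_response.HillFit`."""
    for resp, lig, ec50, se_ec50, etop, se_etop in _FITS:
        if resp == response and lig == ligand:
            return HillFit(etop=etop, ec50=ec50, se_etop=se_etop, se_ec50=se_ec50)
    raise KeyError(f"no bundled fit for response={response!r}, ligand={ligand!r}")


def reference_bias_map(ligands: tuple[str, ...] = ("FGF4", "FGF9")) -> list[dict]:
    """Bias-map rows {ligand, reference, response_num, response_den, label}."""
    rows = []
    for label, num, den in _BIAS_PAIRS:
        for ligand in ligands:
            rows.append(
                {
                    "label": label,
                    "ligand": ligand,
                    "reference": REFERENCE_LIGAND,
                    "response_num": num,
                    "response_den": den,
                }
            )
    return rows
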