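"""Published parameter sets used as fixtures and simulation ground truths.

These are the printed thermodynamic parameters for pressure unfolding of
bovine odorant-binding protein (dimer, engineered monomer, each with and
without the 1-octen-3-ol substrate, in 1.5 M GdnHCl at 25 C), the reported
activation volumes of the monomeric form, and the column constants of the
size-exclusion analysis. No raw spectra, traces or chromatograms were
deposited with the study; these parameter sets are the quantitative anchor
for all synthetic-data generation and consistency checks.
"""

from __future__ import annotations

from typing import NamedTuple


class UnfoldingRow(NamedTuple):
    """One row of the published unfolding-parameter table."""

    protein: str        # "dimer" | "monomer"
    ligand: bool        # substrate present
    branch: str         # "increasing" | "decreasing"
    observable: str     # "csm" | "intensity" | "ans"
    dV_u: float         # ml/mol
    dV_u_se: float
    dG0_u: float        # kJ/mol
    dG0_u_se: float
    p_half_printed: float  # MPa as printed
    exact_printed: bool    # printed with 2 decimals AND correctly rounded


TABLE_UNFOLDING: tuple[UnfoldingRow, ...] = (
    # recorded by increasing pressure
    UnfoldingRow("dimer", False, "increasing", "csm", -34.18, 1.24, 8.37, 0.34, 245.0, False),
    UnfoldingRow("dimer", False, "increasing", "intensity", -58.54, 3.59, 11.98, 0.97, 204.0, False),
    UnfoldingRow("dimer", False, "increasing", "ans", -45.92, 4.52, 7.11, 1.36, 154.0, False),
    UnfoldingRow("dimer", True, "increasing", "csm", -172.60, 5.80, 57.56, 1.93, 333.0, False),
    UnfoldingRow("dimer", True, "increasing", "intensity", -138.70, 8.95, 44.69, 2.90, 322.0, False),
    UnfoldingRow("dimer", True, "increasing", "ans", -114.10, 9.10, 35.19, 4.00, 308.0, False),
    UnfoldingRow("monomer", False, "increasing", "csm", -124.6, 5.53, 13.20, 0.83, 105.0, False),
    UnfoldingRow("monomer", False, "increasing", "intensity", -88.98, 8.27, 11.96, 1.20, 134.0, False),
    UnfoldingRow("monomer", False, "increasing", "ans", -92.17, 4.44, 10.73, 0.57, 116.0, False),
    UnfoldingRow("monomer", True, "increasing", "csm", -82.68, 6.22, 29.15, 2.12, 352.0, False),
    UnfoldingRow("monomer", True, "increasing", "intensity", -88.73, 2.09, 28.65, 2.09, 323.0, False),
    # recorded by decreasing pressure
    UnfoldingRow("dimer", False, "decreasing", "csm", -61.47, 2.95, 4.52, 0.02, 73.53, True),
    UnfoldingRow("dimer", False, "decreasing", "intensity", -78.20, 3.75, 4.76, 0.20, 60.86, False),
    UnfoldingRow("dimer", True, "decreasing", "csm", -95.71, 9.99, 12.63, 1.21, 131.96, True),
    UnfoldingRow("dimer", True, "decreasing", "intensity", -72.58, 9.97, 8.52, 1.27, 117.38, False),
    UnfoldingRow("monomer", False, "decreasing", "csm", -141.90, 15.61, 11.96, 1.36, 84.28, True),
    UnfoldingRow("monomer", True, "decreasing", "csm", -103.30, 10.68, 12.04, 1.32, 116.0, False),
    UnfoldingRow("monomer", True, "decreasing", "intensity", -96.97, 15.41, 9.89, 1.93, 102.0, False),
)

# reported activation volumes of the monomeric (second-cycle) form, ml/mol
DV_ACT_FOLD = 95.0
DV_ACT_FOLD_SE = 8.0
DV_ACT_UNFOLD = -5.5
DV_ACT_UNFOLD_SE = 0.7

# reported crossing pressure of the ln k_f / ln k_u lines, MPa
RATE_LINE_CROSSING_MPA = 180.0

# csm endpoints of the tryptophan transition, nm
CSM_FOLDED_NM = 344.0
CSM_UNFOLDED_NM = 351.0

# intensity observable reference wavelength, nm (native emission maximum)
LAMBDA_REF_NM = 338.0

# SEC column constants (Superose 12) and reported species masses
SEC_V0_ML = 8.0
SEC_VT_ML = 20.8
SEC_DIMER_MASS_DA = 34_800.0
SEC_MONOMER_MASS_DA = 18_970.0

# calibration standards (name, mass in Da) used for the column
SEC_STANDARD_MASSES: tuple[tuple[str, float], ...] = (
    ("beta-amylase", 200_000.0),
    ("alcohol dehydrogenase", 150_000.0),
    ("albumin", 66_000.0),
    ("carbonic anhydrase", 29_000.0),
    ("cytochrome c", 12_400.0),
    ("aprotinin", 6_500.0),
)
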