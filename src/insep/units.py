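"""Unit conversions to the package's canonical units.

Canonical units throughout the package: hormone concentrations in pmol/L,
glucose in mg/dL, time in minutes, amounts in pmol, secretion rates in
pmol/min.  Assay reports commonly use µU/mL (insulin) and ng/mL (C-peptide);
the factors below convert them and can be overridden because two insulin
conventions (6.00 and 6.945 pmol/L per µU/mL) coexist in the literature.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError, SchemaError

#: 1 µU/mL of immunoreactive insulin expressed in pmol/L (WHO convention 1 U = 6 nmol).
INSULIN_UU_PER_ML_TO_PMOL_PER_L = 6.00
#: 1 ng/mL of C-peptide in pmol/L (molecular weight 3020.3 g/mol).
CPEPTIDE_NG_PER_ML_TO_PMOL_PER_L = 331.0
#: 1 U of insulin in pmol (1 U = 6 nmol).
INSULIN_U_TO_PMOL = 6000.0
#: 1 mmol/L of glucose in mg/dL (molecular weight 180.16 g/mol).
GLUCOSE_MMOL_PER_L_TO_MG_PER_DL = 18.016


@dataclass(frozen=True)
class UnitConversionTable:
    """Multiplicative factors from assay units to canonical units."""

    insulin_uU_per_mL_to_pmol_per_L: float = INSULIN_UU_PER_ML_TO_PMOL_PER_L
    cpeptide_ng_per_mL_to_pmol_per_L: float = CPEPTIDE_NG_PER_ML_TO_PMOL_PER_L
    insulin_U_to_pmol: float = INSULIN_U_TO_PMOL
    glucose_mmol_per_L_to_mg_per_dL: float = GLUCOSE_MMOL_PER_L_TO_MG_PER_DL

    def __post_init__(self) -> None:
        for name in (
            "insulin_uU_per_mL_to_pmol_per_L",
            "cpeptide_ng_per_mL_to_pmol_per_L",
            "insulin_U_to_pmol",
            "glucose_mmol_per_L_to_mg_per_dL",
        ):
            if not getattr(self, name) > 0:
                raise DomainError(f"conversion factor {name} must be positive")

    def factor(self, analyte: str, unit: str) -> float:
        """Factor converting ``unit`` of ``analyte`` to the canonical unit."""
        u = unit.strip().replace("µ", "u").replace("μ", "u").lower()
        table = {
            ("insulin", "pmol/l"): 1.0,
            ("insulin", "uu/ml"): self.insulin_uU_per_mL_to_pmol_per_L,
            ("cpeptide", "pmol/l"): 1.0,
            ("cpeptide", "ng/ml"): self.cpeptide_ng_per_mL_to_pmol_per_L,
            ("glucose", "mg/dl"): 1.0,
            ("glucose", "mmol/l"): self.glucose_mmol_per_L_to_mg_per_dL,
        }
        try:
            return table[(analyte, u)]
        except KeyError:
            raise SchemaError(f"unsupported unit {unit!r} for analyte {analyte!r}") from None

    def convert(self, analyte: str, values, unit: str):
        return self.factor(analyte, unit) * values


DEFAULT_UNITS = UnitConversionTable()
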