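"""Population constants for C-peptide kinetics, with provenance.

The population method assigns two-compartment C-peptide kinetic parameters
from demographics alone.  For healthy, non-obese adults the plasma C-peptide
impulse response is a biexponential with a short half-life of 4.95 min
carrying a fraction 0.76 of the decay, a long half-life increasing with age
as ``0.14 * age + 29.2`` min, and an accessible-compartment distribution
volume regressed on body surface area as ``1.92 * BSA + 0.64`` L.

Constant sets for obese and type-2-diabetic populations exist in the same
literature but are not shipped; requesting them raises ``NotImplementedError``.

A JSON or YAML file with the same keys as :data:`VAN_CAUTER_NORMAL` can be
loaded with :func:`load_constants` to override the defaults.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

#: Healthy, non-obese adult population constants (Van Cauter et al.,
#: Diabetes 1992;41:368-77: standardized C-peptide kinetic parameters).
VAN_CAUTER_NORMAL = {
    "short_half_life_min": 4.95,
    "fraction_short": 0.76,
    "long_half_life_intercept_min": 29.2,
    "long_half_life_age_slope_min_per_y": 0.14,
    "volume_slope_L_per_m2": 1.92,
    "volume_intercept_L": 0.64,
    "bsa_formula": "dubois",
    "citation": (
        "Van Cauter E, Mestrez F, Sturis J, Polonsky KS. Estimation of insulin "
        "secretion rates from C-peptide levels: comparison of individual and "
        "standard kinetic parameters for C-peptide clearance. Diabetes 1992."
    ),
}

POPULATION_CONSTANTS = {"normal": VAN_CAUTER_NORMAL}

_REQUIRED_KEYS = (
    "short_half_life_min",
    "fraction_short",
    "long_half_life_intercept_min",
    "long_half_life_age_slope_min_per_y",
    "volume_slope_L_per_m2",
    "volume_intercept_L",
)


def get_constants(category: str) -> dict:
    """Population constant set for a subject category."""
    try:
        return POPULATION_CONSTANTS[category]
    except KeyError:
        raise NotImplementedError(
            f"no population C-peptide kinetic constants shipped for category "
            f"{category!r}; available: {sorted(POPULATION_CONSTANTS)}"
        ) from None


def load_constants(path: Union[str, Path]) -> dict:
    """Load a constants override file (JSON, or YAML if available)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    missing = [k for k in _REQUIRED_KEYS if k not in data]
    if missing:
        raise KeyError(f"constants file {path} lacks key(s) {missing}")
    return data
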