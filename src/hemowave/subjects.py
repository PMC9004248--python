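"""Subject parameter presets for default adults of four ages.

The presets describe hemodynamically stable male adults at ages 20, 40,
60 and 80.  Between ages the vascular Young's modulus rises (stiffer
arteries), blood volume, heart rate and cardiac/vascular properties are
scaled with body surface area.  Values are shipped in a versioned YAML
file and returned verbatim; ages outside the tabulated set are an error
(no interpolation is attempted, since the age dependence of stiffness is
strongly nonlinear).
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import yaml

__all__ = ["SubjectParams", "build_subject", "SUPPORTED_AGES"]

SUPPORTED_AGES = (20, 40, 60, 80)


@dataclasses.dataclass(frozen=True)
class SubjectParams:
    """One subject's physiological parameter set.

    Units: ``height`` cm, ``weight`` kg, ``bsa`` m², ``hr`` beats/min,
    ``blood_volume`` ml, contractilities and stiffnesses mmHg/ml,
    ``svr``/``pvr`` mmHg·s/ml, ``venous_compliance`` ml/mmHg,
    ``youngs_modulus`` mmHg.
    """

    age: float
    height: float
    weight: float
    bsa: float
    hr: float
    blood_volume: float
    lv_contractility: float
    lv_stiffness: float
    rv_contractility: float
    rv_stiffness: float
    svr: float
    pvr: float
    venous_compliance: float
    sys_art_stiffness: float
    pulm_art_stiffness: float
    youngs_modulus: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ValueError(f"SubjectParams.{f.name} must be strictly positive, got {v!r}")


def _load_presets() -> dict:
    text = resources.files("hemowave").joinpath("data/subjects.yaml").read_text()
    return yaml.safe_load(text)


def build_subject(age: int) -> SubjectParams:
    """Return the preset parameter set for a supported age.

    Parameters
    ----------
    age
        One of 20, 40, 60, 80 years.

    Raises
    ------
    ValueError
        For any unsupported age; presets are tabulated, not interpolated.
    """
    if age not in SUPPORTED_AGES:
        raise ValueError(
            f"unsupported age {age!r}: presets exist only for ages {SUPPORTED_AGES}"
        )
    data = _load_presets()["subjects"][str(age)]
    return SubjectParams(**data)
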