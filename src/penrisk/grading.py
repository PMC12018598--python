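"""Histological risk grading for invasive penile squamous cell carcinoma.

The proposed grading scores four histopathological features of the primary
tumor and maps the summed points to a three-level risk group for inguinal
lymph node metastasis (LNM):

* WPOI — worst pattern of invasion, type 1-4; only type 4 (small tumor
  islands of <= 15 cells) scores a point.
* LHR — lymphocytic host response, type 1-3; type 2 scores 1 point,
  type 3 (little or no host response) scores 2.
* LVI — lymphovascular invasion, 1 point when present.
* PNI — perineural invasion, 1 point when present.

Total score 0 -> low risk, 1-2 -> intermediate, >= 3 -> high.

The comparator is the EAU (European Association of Urology) 2014
stratification, which uses pathological stage and WHO grade instead:
pTa and pT1G1 -> low, pT1G2 -> intermediate, pT1G3 or >= pT2 -> high.

The two classifiers deliberately consume disjoint information: the proposed
grading never reads stage or grade, and the EAU grading never reads WPOI or
LHR. The function signatures enforce this separation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Union


class ValidationError(ValueError):
    """An input value violates the domain of a grading parameter."""


class MissingCovariateError(ValidationError):
    """A covariate required by the requested classifier is absent."""


class PTStage(str, enum.Enum):
    """Pathological tumor stage (TNM). pTis is rejected: the grading targets
    invasive carcinoma."""

    pTa = "pTa"
    pT1 = "pT1"
    pT2 = "pT2"
    pT3 = "pT3"
    pT4 = "pT4"


class Grade(str, enum.Enum):
    """WHO histological grade."""

    G1 = "G1"
    G2 = "G2"
    G3 = "G3"


class RiskGroup(str, enum.Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


#: Ascending clinical ordering of the risk groups.
RISK_ORDER = (RiskGroup.LOW, RiskGroup.INTERMEDIATE, RiskGroup.HIGH)


class GradingSystem(str, enum.Enum):
    PROPOSED = "proposed"
    EAU = "eau"


class PT1Sub(str, enum.Enum):
    """pT1 subclassification: pT1a = G1-G2 without LVI or PNI; pT1b = G3
    and/or LVI and/or PNI."""

    pT1a = "pT1a"
    pT1b = "pT1b"


_TRUTHY = {"1", "present", "yes", "true", "y"}
_FALSY = {"0", "absent", "no", "false", "n"}


def parse_presence(value: Union[bool, int, str], field: str = "value") -> bool:
    """Normalize the presence/absence encodings seen in pathology exports.

    Accepts booleans, 0/1, and the strings present/absent, yes/no,
    true/false (case-insensitive).
    """
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if value in (0, 1):
            return bool(value)
        raise ValidationError(f"{field}: numeric presence flag must be 0 or 1, got {value!r}")
    if isinstance(value, str):
        v = value.strip().lower()
        if v in _TRUTHY:
            return True
        if v in _FALSY:
            return False
    raise ValidationError(f"{field}: cannot interpret {value!r} as present/absent")


@dataclass(frozen=True)
class HistopathProfile:
    """The four scored features of one tumor.

    Parameters
    ----------
    wpoi : int
        Worst pattern of invasion, ordinal type 1-4.
    lhr : int
        Lymphocytic host response, ordinal type 1-3.
    lvi : bool
        Lymphovascular invasion present.
    pni : bool
        Perineural invasion present.
    """

    wpoi: int
    lhr: int
    lvi: bool
    pni: bool

    def __post_init__(self) -> None:
        if self.wpoi not in (1, 2, 3, 4):
            raise ValidationError(f"wpoi: must be 1-4, got {self.wpoi!r}")
        if self.lhr not in (1, 2, 3):
            raise ValidationError(f"lhr: must be 1-3, got {self.lhr!r}")
        for field in ("lvi", "pni"):
            if not isinstance(getattr(self, field), bool):
                raise ValidationError(f"{field}: must be a boolean, got {getattr(self, field)!r}")


@dataclass(frozen=True)
class TumorStaging:
    """Stage and (optional) grade; grade is required only by the EAU
    classifier and the pT1a/b subclassification."""

    pt_stage: PTStage
    grade: Optional[Grade] = None

    def __post_init__(self) -> None:
        if not isinstance(self.pt_stage, PTStage):
            raise ValidationError(f"pt_stage: unknown stage {self.pt_stage!r}")
        if self.grade is not None and not isinstance(self.grade, Grade):
            raise ValidationError(f"grade: unknown grade {self.grade!r}")


@dataclass(frozen=True)
class RiskAssessment:
    """A classified tumor: the point score (proposed system only) and the
    risk group."""

    group: RiskGroup
    system: GradingSystem
    score: Optional[int] = None

    def __post_init__(self) -> None:
        if self.system is GradingSystem.PROPOSED:
            if self.score is None or not 0 <= self.score <= 5:
                raise ValidationError(f"score: must be 0-5 for the proposed system, got {self.score!r}")
        elif self.score is not None:
            raise ValidationError("score: EAU assessments carry no point score")


# point contributions per feature; LHR type k contributes k - 1 points
_LHR_POINTS = {1: 0, 2: 1, 3: 2}


def score_profile(profile: HistopathProfile) -> int:
    """Sum the point contributions of the four features (range 0-5)."""
    return (
        (1 if profile.wpoi == 4 else 0)
        + _LHR_POINTS[profile.lhr]
        + (1 if profile.lvi else 0)
        + (1 if profile.pni else 0)
    )


def assign_risk_group(score: int) -> RiskAssessment:
    """Map a total point score to the proposed three-level risk group:
    0 -> low, 1-2 -> intermediate, >= 3 -> high."""
    if not isinstance(score, int) or isinstance(score, bool) or not 0 <= score <= 5:
        raise ValidationError(f"score: must be an integer in [0, 5], got {score!r}")
    if score == 0:
        group = RiskGroup.LOW
    elif score <= 2:
        group = RiskGroup.INTERMEDIATE
    else:
        group = RiskGroup.HIGH
    return RiskAssessment(group=group, system=GradingSystem.PROPOSED, score=score)


def grade_profile(profile: HistopathProfile) -> RiskAssessment:
    """Score a profile and assign its proposed risk group in one step."""
    return assign_risk_group(score_profile(profile))


def eau_risk_group(staging: TumorStaging) -> RiskAssessment:
    """EAU 2014 stratification: pTa / pT1G1 low, pT1G2 intermediate,
    pT1G3 or stage >= pT2 high.

    Raises
    ------
    MissingCovariateError
        For a pT1 tumor without a recorded grade; the stratification is
        undefined there and no default is guessed.
    """
    stage = staging.pt_stage
    if stage is PTStage.pTa:
        group = RiskGroup.LOW
    elif stage is PTStage.pT1:
        if staging.grade is None:
            raise MissingCovariateError("EAU grading of a pT1 tumor requires the WHO grade")
        group = {
            Grade.G1: RiskGroup.LOW,
            Grade.G2: RiskGroup.INTERMEDIATE,
            Grade.G3: RiskGroup.HIGH,
        }[staging.grade]
    else:  # pT2-pT4
        group = RiskGroup.HIGH
    return RiskAssessment(group=group, system=GradingSystem.EAU)


def subclassify_pt1(staging: TumorStaging, profile: HistopathProfile) -> PT1Sub:
    """Split pT1 into pT1a (G1-G2, no LVI, no PNI) and pT1b (G3 and/or
    LVI and/or PNI)."""
    if staging.pt_stage is not PTStage.pT1:
        raise ValidationError(f"subclassification applies to pT1 only, got {staging.pt_stage.value}")
    if staging.grade is None:
        raise MissingCovariateError("pT1 subclassification requires the WHO grade")
    if staging.grade is not Grade.G3 and not profile.lvi and not profile.pni:
        return PT1Sub.pT1a
    return PT1Sub.pT1b
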