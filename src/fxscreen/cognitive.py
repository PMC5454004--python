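"""Executive-function (BRIEF-A-style) score ingestion and profile assembly.

The adult BRIEF inventory yields nine clinical scales on a T-score metric
(population mean 50, SD 10).  Four scales compose the Behavioral Regulation
Index (BRI: Inhibit, Shift, Emotional Control, Self-Monitor), five the
Metacognitive Index (MI: Initiate, Working Memory, Plan/Organize, Task
Monitor, Organization of Materials), and BRI + MI compose the Global
Executive Composite (GEC).  Higher scores mean greater reported difficulty.

This module ingests scale-level scores only (raw item scoring is
proprietary), recomputes the composites with a sum convention, and joins the
15-feature cognitive/demographic block (12 scores + validity composite +
maternal age + maternal education) to the 88-feature linguistic profile to
form the 103-feature comprehensive profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .profiling import LinguisticProfile

__all__ = [
    "BRI_SCALES",
    "MI_SCALES",
    "SCALES",
    "COGNITIVE_FEATURES",
    "CognitiveProfile",
    "ComprehensiveProfile",
    "CognitiveSchemaError",
    "CognitiveValidationError",
    "ProfileJoinError",
    "load_cognitive_table",
    "cognitive_frame",
    "build_comprehensive_profile",
    "build_feature_table",
]

BRI_SCALES = ("inhibit", "shift", "emotional_control", "self_monitor")
MI_SCALES = (
    "initiate",
    "working_memory",
    "plan_organize",
    "task_monitor",
    "organization_of_materials",
)
SCALES = BRI_SCALES + MI_SCALES

#: Serialization order of the 15 cognitive/demographic features.
COGNITIVE_FEATURES = SCALES + (
    "bri",
    "mi",
    "gec",
    "validity",
    "maternal_age",
    "maternal_education",
)

EDUCATION_LEVELS = (1, 2, 3, 4)  # <HS, HS grad, some college/BA, post-BA


class CognitiveSchemaError(ValueError):
    """A required column is missing from the cognitive score table."""


class CognitiveValidationError(ValueError):
    """A value violates its domain (education outside 1-4, composite mismatch)."""


class ProfileJoinError(KeyError):
    """Linguistic and cognitive blocks do not join on participant_id."""


@dataclass(frozen=True)
class CognitiveProfile:
    """One participant's executive-function and demographic block."""

    participant_id: str
    scales: dict[str, float]
    validity: float
    maternal_age: float
    maternal_education: int
    bri: float = None  # type: ignore[assignment]
    mi: float = None  # type: ignore[assignment]
    gec: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        missing = [s for s in SCALES if s not in self.scales]
        if missing:
            raise CognitiveSchemaError(f"missing scales: {missing}")
        if self.maternal_education not in EDUCATION_LEVELS:
            raise CognitiveValidationError(
                f"maternal_education must be in {EDUCATION_LEVELS}, "
                f"got {self.maternal_education}"
            )
        bri = float(sum(self.scales[s] for s in BRI_SCALES))
        mi = float(sum(self.scales[s] for s in MI_SCALES))
        object.__setattr__(self, "bri", bri if self.bri is None else self.bri)
        object.__setattr__(self, "mi", mi if self.mi is None else self.mi)
        object.__setattr__(self, "gec", (bri + mi) if self.gec is None else self.gec)

    def as_vector(self) -> tuple[float, ...]:
        vals = [float(self.scales[s]) for s in SCALES]
        vals += [self.bri, self.mi, self.gec, self.validity]
        vals += [float(self.maternal_age), float(self.maternal_education)]
        return tuple(vals)


def load_cognitive_table(
    source: str | Path | pd.DataFrame,
    composite_tolerance: float = 1e-6,
) -> list[CognitiveProfile]:
    """Load a cognitive score CSV into validated profiles.

    Required columns: participant_id, the nine scales, validity,
    maternal_age, maternal_education.  Optional bri/mi/gec columns are
    checked against the recomputed (sum-convention) composites within
    ``composite_tolerance``.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    required = ("participant_id",) + SCALES + ("validity", "maternal_age", "maternal_education")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CognitiveSchemaError(f"missing required columns: {missing}")

    profiles = []
    for _, row in df.iterrows():
        edu = row["maternal_education"]
        if not float(edu).is_integer() or int(edu) not in EDUCATION_LEVELS:
            raise CognitiveValidationError(
                f"participant {row['participant_id']}: maternal_education "
                f"{edu!r} outside {EDUCATION_LEVELS}"
            )
        profile = CognitiveProfile(
            participant_id=str(row["participant_id"]),
            scales={s: float(row[s]) for s in SCALES},
            validity=float(row["validity"]),
            maternal_age=float(row["maternal_age"]),
            maternal_education=int(edu),
        )
        for name in ("bri", "mi", "gec"):
            if name in df.columns and not pd.isna(row[name]):
                recomputed = getattr(profile, name)
                if abs(float(row[name]) - recomputed) > composite_tolerance:
                    raise CognitiveValidationError(
                        f"participant {profile.participant_id}: provided {name}="
                        f"{row[name]} disagrees with recomputed {recomputed}"
                    )
        profiles.append(profile)
    return profiles


def cognitive_frame(profiles: Sequence[CognitiveProfile]) -> pd.DataFrame:
    """Stack cognitive profiles into a DataFrame indexed by participant_id."""
    frame = pd.DataFrame(
        [p.as_vector() for p in profiles],
        index=[p.participant_id for p in profiles],
        columns=list(COGNITIVE_FEATURES),
    )
    frame.index.name = "participant_id"
    return frame


@dataclass(frozen=True)
class ComprehensiveProfile:
    """The combined 88 + 15 = 103-feature profile for one participant."""

    participant_id: str
    linguistic: LinguisticProfile
    cognitive: CognitiveProfile
    label: Optional[str] = None  # carrier | comparison

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.linguistic.schema.names + COGNITIVE_FEATURES

    @property
    def values(self) -> tuple[float, ...]:
        return self.linguistic.values + self.cognitive.as_vector()

    def as_series(self) -> pd.Series:
        return pd.Series(
            self.values, index=list(self.feature_names), name=self.participant_id
        )


def build_comprehensive_profile(
    lp: LinguisticProfile,
    cp: CognitiveProfile,
    label: Optional[str] = None,
) -> ComprehensiveProfile:
    """Concatenate linguistic and cognitive blocks for one participant."""
    if lp.participant_id and lp.participant_id != cp.participant_id:
        raise ProfileJoinError(
            f"participant_id mismatch: linguistic {lp.participant_id!r} "
            f"vs cognitive {cp.participant_id!r}"
        )
    return ComprehensiveProfile(
        participant_id=cp.participant_id, linguistic=lp, cognitive=cp, label=label
    )


def build_feature_table(
    linguistic: pd.DataFrame,
    cognitive: pd.DataFrame,
    labels: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Join linguistic and cognitive feature frames on participant_id.

    Raises :class:`ProfileJoinError` naming the participants missing from
    either side.  When ``labels`` is given a final ``label`` column is added.
    """
    missing_cog = sorted(set(linguistic.index) - set(cognitive.index))
    missing_lin = sorted(set(cognitive.index) - set(linguistic.index))
    if missing_cog or missing_lin:
        raise ProfileJoinError(
            f"unmatched participants (no cognitive row: {missing_cog}; "
            f"no linguistic row: {missing_lin})"
        )
    table = linguistic.join(cognitive)
    if labels is not None:
        missing_lab = sorted(set(table.index) - set(labels.index))
        if missing_lab:
            raise ProfileJoinError(f"participants without label: {missing_lab}")
        table = table.assign(label=labels.reindex(table.index))
    return table
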