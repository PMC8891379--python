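"""Deterministic dietary-exposure and cancer-risk equations.

The chain is the standard ingestion-pathway model:

* ``BEC = sum_i C_i * TEF_i`` — benzo[a]pyrene-equivalent concentration,
  converting each congener's concentration into BaP potency units;
* ``EDI = C * IR * EF * ED / (BW * AT)`` — estimated daily intake in
  mg per kg body weight per day;
* ``ILCR`` — incremental lifetime cancer risk, the BaP-equivalent daily
  dose multiplied by the oral cancer slope factor SF (7.3 per mg/kg/day
  for BaP).

Two ILCR conventions are provided.  ``dose_consistent`` (default)
computes ``EDI(BEC) * SF``, i.e. includes the intake rate IR so the
slope factor multiplies a true dose.  ``study_verbatim`` reproduces the
source study's printed formula ``BEC*EF*ED*SF/(BW*AT)``, which omits IR
and is therefore dimensionally a risk per unit concentration; it is kept
for fidelity and comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .core import ValidationError, convert_concentration, DEFAULT_TEFS

__all__ = [
    "TefSet",
    "NISBET_LAGOY",
    "ExposureParams",
    "DEFAULT_PARAMS",
    "RiskResult",
    "bec",
    "edi",
    "ilcr",
    "classify_risk",
    "jecfa_flag",
    "assess",
    "ZONE_SAFE",
    "ZONE_INTERMEDIATE",
    "ZONE_THRESHOLD",
    "ZONE_SIGNIFICANT",
    "JECFA_LIMIT_MG_PER_KG_DAY",
]

ILCR_MODES = ("dose_consistent", "study_verbatim")

#: JECFA health-concern trigger: 10 ng BaP /kg bw/day, expressed in mg.
JECFA_LIMIT_MG_PER_KG_DAY = 1e-5

ZONE_SAFE = "safe"
ZONE_INTERMEDIATE = "intermediate"
ZONE_THRESHOLD = "threshold_exceeded"
ZONE_SIGNIFICANT = "significant_danger"


@dataclass(frozen=True)
class TefSet:
    """Named mapping from congener abbreviation to TEF (BaP = 1)."""

    name: str
    tefs: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.tefs.values()):
            raise ValidationError(f"{self.name}: TEFs must be >= 0")

    def __getitem__(self, abbrev: str) -> float:
        return self.tefs[abbrev]

    def __contains__(self, abbrev: str) -> bool:
        return abbrev in self.tefs


NISBET_LAGOY = TefSet(name="Nisbet-LaGoy", tefs=dict(DEFAULT_TEFS))


@dataclass(frozen=True)
class ExposureParams:
    """Point exposure parameters of the ingestion pathway.

    Units: ``c`` mg contaminant per kg food (optional — supply per call
    for per-congener work); ``ir`` kg food/day; ``ef`` days/year; ``ed``
    years; ``bw`` kg body weight; ``at`` days; ``sf`` per mg/kg/day.
    The defaults carry the study's stated BW (70 kg) and SF (7.3) and an
    intake calibrated so IR*EF*ED/(BW*AT) = 1.86e-4 per day, the study's
    constant median-EDI-to-concentration ratio.
    """

    ir: float = 0.01302
    ef: float = 365.0
    ed: float = 1.0
    bw: float = 70.0
    at: float = 365.0
    sf: float = 7.3
    c: float | None = None

    def __post_init__(self) -> None:
        for name in ("ir", "ef", "ed", "bw", "at", "sf"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.c is not None and self.c < 0:
            raise ValidationError("c must be >= 0")

    @property
    def intake_factor(self) -> float:
        """IR*EF*ED/(BW*AT): daily intake per unit food concentration (1/day)."""
        return self.ir * self.ef * self.ed / (self.bw * self.at)


DEFAULT_PARAMS = ExposureParams()


def bec(
    concentrations: Mapping[str, float],
    tefs: TefSet = NISBET_LAGOY,
) -> tuple[float, dict[str, float] | None]:
    """BaP-equivalent concentration and per-congener contribution shares.

    ``concentrations`` may be in any single unit; the BEC comes back in
    the same unit.  Contribution fractions sum to 1; they are ``None``
    (undefined) when the total is zero.
    """
    missing = [a for a in concentrations if a not in tefs]
    if missing:
        raise ValidationError(f"no TEF for congeners: {missing}")
    terms = {a: c * tefs[a] for a, c in concentrations.items()}
    total = float(sum(terms.values()))
    if total == 0.0:
        return 0.0, None
    contributions = {a: t / total for a, t in terms.items()}
    return total, contributions


def edi(params: ExposureParams, c: float | None = None) -> float:
    """Estimated daily intake, mg/(kg bw * day).

    ``c`` (mg contaminant per kg food) overrides ``params.c``.
    """
    c_eff = params.c if c is None else c
    if c_eff is None:
        raise ValidationError("no concentration supplied (params.c or c argument)")
    if c_eff < 0:
        raise ValidationError("concentration must be >= 0")
    return c_eff * params.intake_factor


def ilcr(
    bec_mg_per_kg: float,
    params: ExposureParams = DEFAULT_PARAMS,
    mode: str = "dose_consistent",
) -> float:
    """Incremental lifetime cancer risk from a BaP-equivalent concentration."""
    if mode not in ILCR_MODES:
        raise ValidationError(f"unknown ILCR mode {mode!r}; use {ILCR_MODES}")
    if bec_mg_per_kg < 0:
        raise ValidationError("BEC must be >= 0")
    if mode == "study_verbatim":
        return bec_mg_per_kg * params.ef * params.ed * params.sf / (params.bw * params.at)
    return edi(params, c=bec_mg_per_kg) * params.sf


def classify_risk(ilcr_value: float) -> str:
    """Map an ILCR to the conventional risk zone.

    ``< 1e-6`` safe; ``[1e-6, 1e-4]`` intermediate (below the threshold
    limit); ``(1e-4, 1e-3]`` threshold exceeded; ``> 1e-3`` significant
    danger.  Boundary values belong to the lower (less alarming) zone.
    """
    if ilcr_value < 0:
        raise ValidationError("ILCR must be >= 0")
    if ilcr_value < 1e-6:
        return ZONE_SAFE
    if ilcr_value <= 1e-4:
        return ZONE_INTERMEDIATE
    if ilcr_value <= 1e-3:
        return ZONE_THRESHOLD
    return ZONE_SIGNIFICANT


def jecfa_flag(edi_bap_mg_per_kg_day: float) -> bool:
    """True iff the BaP daily intake strictly exceeds 10 ng/kg bw/day."""
    return edi_bap_mg_per_kg_day > JECFA_LIMIT_MG_PER_KG_DAY


@dataclass(frozen=True)
class RiskResult:
    """Bundle of the deterministic risk chain for one concentration vector."""

    bec_ug_per_kg: float
    bec_mg_per_kg: float
    bec_contributions: dict[str, float] | None
    edi_mg_per_kg_day: dict[str, float]
    edi_bap: float
    ilcr: float
    zone: str
    jecfa_exceeded: bool
    mode: str


def assess(
    concentrations_ug_per_kg: Mapping[str, float],
    tefs: TefSet = NISBET_LAGOY,
    params: ExposureParams = DEFAULT_PARAMS,
    mode: str = "dose_consistent",
) -> RiskResult:
    """Run the full deterministic chain on a ug/kg concentration vector."""
    conc_mg = {
        a: convert_concentration(v, "ug/kg", "mg/kg")
        for a, v in concentrations_ug_per_kg.items()
    }
    bec_mg, contrib = bec(conc_mg, tefs)
    edis = {a: edi(params, c=c) for a, c in conc_mg.items()}
    risk = ilcr(bec_mg, params, mode=mode)
    return RiskResult(
        bec_ug_per_kg=convert_concentration(bec_mg, "mg/kg", "ug/kg"),
        bec_mg_per_kg=bec_mg,
        bec_contributions=contrib,
        edi_mg_per_kg_day=edis,
        edi_bap=edis.get("BaP", 0.0),
        ilcr=risk,
        zone=classify_risk(risk),
        jecfa_exceeded=jecfa_flag(edis.get("BaP", 0.0)),
        mode=mode,
    )
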