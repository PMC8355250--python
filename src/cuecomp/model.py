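"""Positivity-biased Rescorla-Wagner learning over elemental and configural units.

The model is the standard delta rule with a summed (aggregate)
prediction: on a trial with active units ``S`` and outcome ``r`` in
{0, 1},

    delta = lambda * r - sum_{i in S} V_i
    V_i  <- V_i + alpha_i * beta * w(delta) * delta      for i in S

where ``w(delta)`` is ``w_pos`` for positive prediction errors and
``w_neg`` for negative ones.  Self-initiated (agency) training is
modelled as a positivity bias, ``w_pos > w_neg``; yoked passive
training weights both signs equally (``w_pos = w_neg``).  Asymmetric
weighting of the PE inside the learning term is algebraically the same
as a sign-dependent learning rate.

Stimulus representation is elemental by default; a compound may
additionally activate a configural unit unique to it (needed for
patterning discriminations) and an always-present context unit can be
switched on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "RepresentationConfig",
    "ModelParams",
    "AssociativeState",
    "CONTEXT_UNIT",
    "configural_unit",
    "active_units",
    "prediction",
    "rw_update",
    "closed_form_single_cue",
    "agency_params",
    "passive_params",
    "bias_params",
    "default_representation",
]

CONTEXT_UNIT = "ctx"

#: default elemental salience; small enough that discrimination learning
#: stays preasymptotic over hundreds of massed trials (see docs/methods.md)
DEFAULT_ALPHA = 0.003

#: default PE-sign weights.  Agency amplifies positive-PE learning and
#: discounts negative-PE learning; the passive weight sits between the
#: two, so yoked training is slower on positive PEs but harder on
#: negative ones (see docs/methods.md for the calibration).
DEFAULT_W_POS_AGENCY = 1.0
DEFAULT_W_NEG_AGENCY = 0.25
DEFAULT_W_PASSIVE = 0.45

#: total PE weight w_pos + w_neg along the one-parameter bias family;
#: the agency default (1.0, 0.25) lies on this line at ratio 0.25
DEFAULT_TOTAL_WEIGHT = 1.25

#: default salience of configural units relative to elemental cues where
#: configural units are enabled
DEFAULT_CONFIGURAL_SCALE = 3.0


def configural_unit(cues: Iterable[str]) -> str:
    """Name of the configural unit for a compound, e.g. ``c(AX)``."""
    return "c(" + "".join(sorted(cues)) + ")"


@dataclass(frozen=True)
class RepresentationConfig:
    """Which stimulus units a trial's cues activate.

    ``configural_salience_scale`` is the salience of configural units
    relative to the elemental salience.
    """

    use_configural_units: bool = False
    use_context_unit: bool = False
    configural_salience_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.configural_salience_scale <= 0:
            raise ValueError("configural_salience_scale must be positive")


@dataclass(frozen=True)
class ModelParams:
    """Learning-rule parameters for one group / condition.

    Parameters
    ----------
    lam:
        Asymptote of conditioning (unitless), default 1.
    alpha:
        Elemental salience in (0, 1], or a per-unit mapping; units
        absent from the mapping fall back to ``default_alpha``.
    beta:
        Base learning rate in (0, 1] (reinforcer-driven; folded with
        alpha into a single effective rate in practice).
    w_pos, w_neg:
        Non-negative weights on positive / negative prediction errors.
        ``w_pos > w_neg`` is the agency positivity bias; equality is the
        unbiased (passive) rule.
    """

    lam: float = 1.0
    alpha: float | Mapping[str, float] = DEFAULT_ALPHA
    beta: float = 1.0
    w_pos: float = 1.0
    w_neg: float = 1.0
    default_alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        alphas = (
            [self.alpha] if isinstance(self.alpha, (int, float))
            else list(self.alpha.values()) + [self.default_alpha]
        )
        if not alphas or any(not 0 < a <= 1 for a in alphas):
            raise ValueError("salience alpha must lie in (0, 1]")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must lie in (0, 1]")
        if self.w_pos < 0 or self.w_neg < 0:
            raise ValueError("PE weights must be non-negative")
        if max(alphas) * self.beta * max(self.w_pos, self.w_neg) > 1:
            raise ValueError(
                "alpha*beta*max(w_pos, w_neg) must be <= 1 for bounded, "
                "non-oscillating single-cue learning"
            )

    def alpha_for(self, unit: str,
                  rep: RepresentationConfig | None = None) -> float:
        """Salience of ``unit``; configural units are scaled by the rep config."""
        if isinstance(self.alpha, (int, float)):
            a = float(self.alpha)
        else:
            a = float(self.alpha.get(unit, self.default_alpha))
        if rep is not None and unit.startswith("c("):
            a *= rep.configural_salience_scale
        return a

    @property
    def bias_ratio(self) -> float:
        """w_neg / w_pos; 1 means unbiased, < 1 a positivity bias."""
        return self.w_neg / self.w_pos


def agency_params(
    alpha: float | Mapping[str, float] = DEFAULT_ALPHA,
    w_pos: float = DEFAULT_W_POS_AGENCY,
    w_neg: float = DEFAULT_W_NEG_AGENCY,
    lam: float = 1.0,
    beta: float = 1.0,
) -> ModelParams:
    """Default agency-condition parameters (positivity bias, w_pos > w_neg)."""
    return ModelParams(lam=lam, alpha=alpha, beta=beta, w_pos=w_pos, w_neg=w_neg)


def passive_params(
    alpha: float | Mapping[str, float] = DEFAULT_ALPHA,
    w: float = DEFAULT_W_PASSIVE,
    lam: float = 1.0,
    beta: float = 1.0,
) -> ModelParams:
    """Default passive-condition parameters (symmetric PE weighting).

    The common weight lies between the agency condition's w_neg and
    w_pos: relative to yoked training, agency amplifies learning from
    positive PEs and discounts learning from negative ones.
    """
    return ModelParams(lam=lam, alpha=alpha, beta=beta, w_pos=w, w_neg=w)


def bias_params(
    ratio: float,
    total_weight: float = DEFAULT_TOTAL_WEIGHT,
    alpha: float | Mapping[str, float] = DEFAULT_ALPHA,
    lam: float = 1.0,
    beta: float = 1.0,
) -> ModelParams:
    """Parameters along the one-parameter positivity-bias family.

    The bias reallocates a fixed total PE weight between the two signs:
    ``w_pos = total_weight / (1 + ratio)`` and ``w_neg = ratio * w_pos``,
    so ``ratio = w_neg / w_pos`` while ``w_pos + w_neg`` stays constant.
    ``ratio = 1`` is the unbiased (passive-like) rule; decreasing the
    ratio tilts learning toward positive PEs without changing the
    overall learning budget.  The agency default lies on this family at
    ratio 0.25.
    """
    if not 0 < ratio <= 1:
        raise ValueError("bias ratio must lie in (0, 1]")
    w_pos = total_weight / (1.0 + ratio)
    return ModelParams(
        lam=lam, alpha=alpha, beta=beta, w_pos=w_pos, w_neg=ratio * w_pos
    )


def default_representation(experiment_id: str) -> RepresentationConfig:
    """Per-design default stimulus representation.

    Patterning (exp4) requires configural units to be solvable, and they
    carry a higher salience than the elements (compounds are more
    distinctive than their parts); the blocking/competition designs are
    treated elementally.
    """
    if experiment_id == "exp4_patterning":
        return RepresentationConfig(
            use_configural_units=True,
            configural_salience_scale=DEFAULT_CONFIGURAL_SCALE,
        )
    return RepresentationConfig()


@dataclass
class AssociativeState:
    """Per-unit associative strengths; absent units have strength 0."""

    V: dict[str, float] = field(default_factory=dict)

    def strength(self, unit: str) -> float:
        return self.V.get(unit, 0.0)

    def copy(self) -> "AssociativeState":
        return AssociativeState(dict(self.V))


def active_units(
    trial_cues: Iterable[str], rep: RepresentationConfig | None = None
) -> tuple[str, ...]:
    """Units activated by a trial's cue set under a representation config."""
    cues = sorted(set(trial_cues))
    if not cues:
        raise ValueError("trial_cues must be nonempty")
    rep = rep or RepresentationConfig()
    units = list(cues)
    if rep.use_configural_units and len(cues) > 1:
        units.append(configural_unit(cues))
    if rep.use_context_unit:
        units.append(CONTEXT_UNIT)
    return tuple(units)


def prediction(state: AssociativeState, units: Iterable[str]) -> float:
    """Aggregate prediction: the summed strength of the active units."""
    return sum(state.V.get(u, 0.0) for u in units)


def rw_update(
    state: AssociativeState,
    units: Iterable[str],
    reinforced: bool,
    params: ModelParams,
    rep: RepresentationConfig | None = None,
) -> AssociativeState:
    """One delta-rule update; returns a new state, inputs untouched.

    A zero prediction error leaves the state unchanged (the update is a
    no-op at the asymptote fixed point).
    """
    units = tuple(units)
    delta = params.lam * (1.0 if reinforced else 0.0) - prediction(state, units)
    new = state.copy()
    if delta == 0.0:
        return new
    w = params.w_pos if delta > 0 else params.w_neg
    for u in units:
        new.V[u] = new.V.get(u, 0.0) + params.alpha_for(u, rep) * params.beta * w * delta
    return new


def closed_form_single_cue(t: int, effective_rate: float, lam: float = 1.0) -> float:
    """Analytic acquisition curve for one continuously reinforced cue.

    After ``t`` reinforced trials at effective rate
    ``alpha * beta * w_pos``, V equals ``lam * (1 - (1 - rate)^t)``.
    """
    if not 0 < effective_rate <= 1:
        raise ValueError("effective_rate must lie in (0, 1]")
    if t < 0:
        raise ValueError("trial count must be non-negative")
    return lam * (1.0 - (1.0 - effective_rate) ** t)
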