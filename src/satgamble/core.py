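"""Domain types for standard-gamble elicitation of life-satisfaction utilities.

The survey instrument offers a certain ("baseline") life state against a
lottery between a better ("win") and a worse ("lose") state, walking the
probability of the worse outcome down a fixed grid until the respondent
accepts. These types model the six ordinal life states (death plus five
described life situations), the gamble design, the resulting decision
ladders, and the binned population distribution of life satisfaction used
for aggregation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping, Sequence


class State(enum.IntEnum):
    """Ordinal life states, ascending. ``F`` is death; ``E``–``A`` are the
    described life situations from worst to best."""

    F = 0
    E = 1
    D = 2
    C = 3
    B = 4
    A = 5

    @property
    def rank(self) -> int:
        return int(self)

    @property
    def is_death(self) -> bool:
        return self is State.F


#: Living states in ascending order of life satisfaction.
LIVING_STATES: tuple[State, ...] = (State.E, State.D, State.C, State.B, State.A)

#: States with no physical-health limitation (the "phys health" subset).
PHYS_HEALTH_STATES: frozenset[State] = frozenset(
    {State.D, State.C, State.B, State.A}
)

#: Descending probability-of-loss grid, stored as exact strings to avoid
#: float drift in files; parsed to floats on demand.
PROBABILITY_GRID_LABELS: tuple[str, ...] = (
    "1/2",
    "1/5",
    "1/10",
    "1/100",
    "1/1000",
    "1/10000",
    "1/100000",
    "1/1000000",
)

PROBABILITY_GRID: tuple[float, ...] = tuple(
    float(Fraction(lbl)) for lbl in PROBABILITY_GRID_LABELS
)

_LABEL_TO_PROB: dict[str, float] = dict(
    zip(PROBABILITY_GRID_LABELS, PROBABILITY_GRID)
)


def grid_probability(label: str) -> float:
    """Parse a grid label such as ``"1/100"`` to its float probability."""
    try:
        return _LABEL_TO_PROB[label]
    except KeyError:
        raise FormatError(f"probability {label!r} is not on the ladder grid")


class Decision(str, enum.Enum):
    ACCEPT = "accept"
    REJECT = "reject"
    CANT_CHOOSE = "cant_choose"


class Context(str, enum.Enum):
    PERSONAL = "personal"
    SOCIETAL = "societal"


class Block(str, enum.Enum):
    ADJACENT_PERSONAL = "adjacent_personal"
    ADJACENT_SOCIETAL = "adjacent_societal"
    NONADJACENT_PERSONAL = "nonadjacent_personal"


class PointStatus(str, enum.Enum):
    INTERIOR = "interior"
    INFINITE_AVERSION = "infinite_aversion"
    MAXIMAL_TOLERANCE = "maximal_tolerance"
    UNDECIDABLE = "undecidable"


class Anchoring(str, enum.Enum):
    #: U_F = 0, U_E = 1 — the well-conditioned scale used while solving.
    ESTIMATION = "estimation"
    #: U_F = 0, U_A = 1 — the scale used when reporting curves.
    REPORTING = "reporting"


class ValidationError(ValueError):
    """An object violates a domain invariant."""


class SchemaError(ValidationError):
    """A file is missing required columns or uses unknown categories."""


class FormatError(ValidationError):
    """A file value cannot be parsed (e.g. off-grid probability)."""


@dataclass(frozen=True)
class GambleSpec:
    """One standard gamble: keep ``baseline`` for sure, or accept a lottery
    winning ``win`` with probability 1−p and losing to ``lose`` with
    probability p."""

    baseline: State
    win: State
    lose: State
    context: Context
    block: Block

    def __post_init__(self) -> None:
        if not (self.lose.rank < self.baseline.rank < self.win.rank):
            raise ValidationError(
                f"gamble states must satisfy lose < baseline < win, got "
                f"{self.lose.name} < {self.baseline.name} < {self.win.name}"
            )
        up = self.win.rank - self.baseline.rank
        down = self.baseline.rank - self.lose.rank
        if self.block in (Block.ADJACENT_PERSONAL, Block.ADJACENT_SOCIETAL):
            if up != 1 or down != 1:
                raise ValidationError(
                    f"adjacent-block gamble must have one-step arms, got "
                    f"up={up}, down={down}"
                )
        else:
            if max(up, down) < 2 or max(up, down) > 3:
                raise ValidationError(
                    "nonadjacent-block gamble needs an arm 2–3 steps from "
                    f"baseline, got up={up}, down={down}"
                )

    @property
    def involves_death(self) -> bool:
        return self.lose.is_death

    @property
    def phys_health_only(self) -> bool:
        states = {self.baseline, self.win, self.lose}
        return states <= PHYS_HEALTH_STATES

    def key(self) -> tuple:
        return (
            self.context.value,
            self.block.value,
            self.baseline.name,
            self.win.name,
            self.lose.name,
        )


def adjacent_gamble(baseline: State, context: Context) -> GambleSpec:
    """The chained-ladder gamble anchored at ``baseline``: win one step up,
    lose one step down."""
    block = (
        Block.ADJACENT_PERSONAL
        if context is Context.PERSONAL
        else Block.ADJACENT_SOCIETAL
    )
    return GambleSpec(
        baseline=baseline,
        win=State(baseline.rank + 1),
        lose=State(baseline.rank - 1),
        context=context,
        block=block,
    )


#: Baselines of the four chained adjacent gambles, in chaining order.
CHAIN_BASELINES: tuple[State, ...] = (State.E, State.D, State.C, State.B)


@dataclass(frozen=True)
class LadderResponse:
    """Ordered accept/reject/can't-choose decisions for one gamble, walked
    down the probability grid from 1/2.

    Presentation stops after the first accept, after the lowest grid value,
    or after two consecutive can't-choose responses (undecidable). A single
    can't-choose is followed by the next lower probability.
    """

    gamble: GambleSpec
    decisions: tuple[tuple[str, Decision], ...]

    def __post_init__(self) -> None:
        if not self.decisions:
            raise ValidationError("ladder has no decisions")
        labels = [lbl for lbl, _ in self.decisions]
        expected = PROBABILITY_GRID_LABELS[: len(labels)]
        if tuple(labels) != expected:
            raise ValidationError(
                f"ladder probabilities must walk the grid from 1/2, got "
                f"{labels}"
            )
        for i, (_, dec) in enumerate(self.decisions):
            last = i == len(self.decisions) - 1
            if dec is Decision.ACCEPT and not last:
                raise ValidationError("decisions continue after an accept")
            if (
                dec is Decision.CANT_CHOOSE
                and i > 0
                and self.decisions[i - 1][1] is Decision.CANT_CHOOSE
                and not last
            ):
                raise ValidationError(
                    "decisions continue after two consecutive can't-choose"
                )
        final = self.decisions[-1][1]
        full = len(self.decisions) == len(PROBABILITY_GRID_LABELS)
        if final is Decision.REJECT and not full:
            raise ValidationError("ladder ends on a reject before the grid end")
        if final is Decision.CANT_CHOOSE and not (self.undecidable or full):
            raise ValidationError(
                "ladder ends on a single can't-choose before the grid end"
            )

    @property
    def undecidable(self) -> bool:
        """True if indecision persisted: two consecutive can't-choose, or a
        can't-choose at the lowest grid value with nothing lower to offer."""
        decs = [d for _, d in self.decisions]
        for a, b in zip(decs, decs[1:]):
            if a is Decision.CANT_CHOOSE and b is Decision.CANT_CHOOSE:
                return True
        return (
            decs[-1] is Decision.CANT_CHOOSE
            and len(decs) == len(PROBABILITY_GRID_LABELS)
        )

    def accepted_probabilities(self) -> list[float]:
        return [
            grid_probability(lbl)
            for lbl, d in self.decisions
            if d is Decision.ACCEPT
        ]

    def rejected_probabilities(self) -> list[float]:
        return [
            grid_probability(lbl)
            for lbl, d in self.decisions
            if d is Decision.REJECT
        ]


@dataclass(frozen=True)
class IndifferencePoint:
    """Log-midpoint indifference probability for one ladder.

    ``p`` is the geometric mean of the highest accepted and lowest rejected
    grid probabilities, with the conventions p_accept=0 when every step was
    rejected (infinite aversion) and p_reject=1 when the first step was
    accepted (maximal tolerance). Undecidable ladders carry no ``p``.
    """

    p: float | None
    status: PointStatus

    def __post_init__(self) -> None:
        if self.status is PointStatus.UNDECIDABLE:
            if self.p is not None:
                raise ValidationError("undecidable point must not carry p")
            return
        if self.p is None or not (0.0 <= self.p < 1.0):
            raise ValidationError(f"indifference p out of range: {self.p}")
        if (self.status is PointStatus.INFINITE_AVERSION) != (self.p == 0.0):
            raise ValidationError("infinite_aversion <=> p == 0")
        if self.status is PointStatus.MAXIMAL_TOLERANCE and not math.isclose(
            self.p, math.sqrt(0.5)
        ):
            raise ValidationError("maximal_tolerance requires p = sqrt(1/2)")


@dataclass(frozen=True)
class UtilityCurve:
    """Per-participant utilities of the six states under a stated anchoring."""

    participant: str
    utilities: Mapping[State, float]
    anchoring: Anchoring

    def __post_init__(self) -> None:
        object.__setattr__(self, "utilities", dict(self.utilities))
        vals = [self.utilities[s] for s in sorted(self.utilities)]
        if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
            raise ValidationError("utilities must be nondecreasing in rank")

    def value(self, state: State) -> float:
        return self.utilities[state]

    def as_vector(self) -> list[float]:
        return [self.utilities[s] for s in sorted(self.utilities)]


@dataclass(frozen=True)
class LossAversionRecord:
    """Loss aversion λ for one gamble and its bounded transform λ′."""

    gamble: GambleSpec
    lam: float
    lam_prime: float

    def __post_init__(self) -> None:
        if not (self.lam > 0):
            raise ValidationError("lambda must be positive (or +inf)")
        expected = 1.0 if math.isinf(self.lam) else (self.lam - 1) / (self.lam + 1)
        if abs(self.lam_prime - expected) > 1e-9:
            raise ValidationError("lambda_prime inconsistent with lambda")


@dataclass(frozen=True)
class Respondent:
    """One survey participant: demographics, political items, vignette
    life-satisfaction ratings and the twelve gamble ladders."""

    id: str
    condition: str  # "gambles_first" | "ls_first"
    age_band: str
    sex: str
    party: str
    political_items: tuple[int, ...]
    vignette_ratings: Mapping[State, int]
    ladders: tuple[LadderResponse, ...]
    attention_fail: bool = False

    def __post_init__(self) -> None:
        if self.condition not in ("gambles_first", "ls_first"):
            raise ValidationError(f"unknown condition {self.condition!r}")
        if len(self.political_items) != 5:
            raise ValidationError("exactly five political items required")
        object.__setattr__(self, "vignette_ratings", dict(self.vignette_ratings))
        if set(self.vignette_ratings) != set(LIVING_STATES):
            raise ValidationError("vignette ratings must cover states A–E")
        for s, r in self.vignette_ratings.items():
            if not (0 <= int(r) <= 10):
                raise ValidationError(f"rating for {s.name} out of 0–10: {r}")
        counts = {b: 0 for b in Block}
        for lad in self.ladders:
            counts[lad.gamble.block] += 1
        if (
            len(self.ladders) != 12
            or counts[Block.ADJACENT_PERSONAL] != 4
            or counts[Block.ADJACENT_SOCIETAL] != 4
            or counts[Block.NONADJACENT_PERSONAL] != 4
        ):
            raise ValidationError(
                "respondent needs 12 ladders: 4 adjacent personal, 4 adjacent "
                f"societal, 4 nonadjacent personal; got {counts}"
            )

    @property
    def political_score(self) -> int:
        """Sum of the five attitude items (leftwards-positive)."""
        return int(sum(self.political_items))

    @property
    def order_violation(self) -> bool:
        """True when the vignette ratings are not monotone A ≥ B ≥ C ≥ D ≥ E."""
        r = self.vignette_ratings
        ordered = [r[s] for s in reversed(LIVING_STATES)]  # A, B, C, D, E
        return any(b > a for a, b in zip(ordered, ordered[1:]))

    def ladders_in(
        self, context: Context, blocks: Iterable[Block] | None = None
    ) -> list[LadderResponse]:
        blocks = set(blocks) if blocks is not None else None
        return [
            lad
            for lad in self.ladders
            if lad.gamble.context is context
            and (blocks is None or lad.gamble.block in blocks)
        ]

    def adjacent_ladders(self, context: Context) -> list[LadderResponse]:
        """The four chained-ladder responses of a context, in chaining order
        (baseline E, D, C, B)."""
        block = (
            Block.ADJACENT_PERSONAL
            if context is Context.PERSONAL
            else Block.ADJACENT_SOCIETAL
        )
        found = {
            lad.gamble.baseline: lad
            for lad in self.ladders
            if lad.gamble.block is block
        }
        return [found[b] for b in CHAIN_BASELINES]


#: ONS-style life-satisfaction bin labels, low to high.
LS_BIN_LABELS: tuple[str, ...] = ("0-4", "5-6", "7-8", "9-10")

#: Default within-bin representative values (bin midpoints).
DEFAULT_BIN_REPRESENTATIVES: tuple[float, ...] = (2.0, 5.5, 7.5, 9.5)


@dataclass(frozen=True)
class BinnedLSDistribution:
    """Population shares over the life-satisfaction ranges 0–4, 5–6, 7–8,
    9–10, with a representative scale value per bin."""

    shares: tuple[float, ...]
    representatives: tuple[float, ...] = DEFAULT_BIN_REPRESENTATIVES

    def __post_init__(self) -> None:
        if len(self.shares) != len(LS_BIN_LABELS):
            raise ValidationError(
                f"expected {len(LS_BIN_LABELS)} bin shares, got "
                f"{len(self.shares)}"
            )
        if any(s < 0 for s in self.shares):
            raise ValidationError("bin shares must be nonnegative")
        if abs(sum(self.shares) - 1.0) > 1e-9:
            raise ValidationError(
                f"bin shares must sum to 1, got {sum(self.shares)!r}"
            )
        if len(self.representatives) != len(LS_BIN_LABELS):
            raise ValidationError("one representative value per bin required")
        for lo_hi, rep in zip(LS_BIN_LABELS, self.representatives):
            lo, hi = (float(x) for x in lo_hi.split("-"))
            if not (lo <= rep <= hi):
                raise ValidationError(
                    f"representative {rep} outside bin {lo_hi}"
                )

    @property
    def mean_ls(self) -> float:
        """Mean life satisfaction under the bin-representative convention."""
        return float(
            sum(s * r for s, r in zip(self.shares, self.representatives))
        )

    def with_representatives(
        self, representatives: Sequence[float]
    ) -> "BinnedLSDistribution":
        return replace(self, representatives=tuple(representatives))
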