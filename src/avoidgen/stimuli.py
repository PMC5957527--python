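"""Stimulus space and trial sequences for the avoidance generalization task.

Stimuli are flower-like shapes parameterized by a single "spikiness"
coordinate ``rho`` in (0, 1) along a perceptually linear axis.  The default
design places two CS+ (shocked on 80% of unavoided trials) at rho 0.25 and
0.75, one CS- (always safe), and one generalization stimulus (GS) on each
side of each CS+ at a distance ``theta`` — the individually titrated
75%-discriminability step.  GS trials are structurally never reinforced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "Stimulus",
    "TaskDesign",
    "TrialSequence",
    "InvalidDesignError",
    "SequencingError",
    "build_design",
    "generate_sequence",
]

AVERSIVE = -1
NEUTRAL = 0

#: rho step between GS and adjacent CS+ measured in the laboratory sample
THETA_FMRI = 0.071
#: rho step used for every online (crowdsourced) participant
THETA_AMT = 0.065


class Role(str, Enum):
    CS_PLUS = "CS_PLUS"
    CS_MINUS = "CS_MINUS"
    GS = "GS"


class InvalidDesignError(ValueError):
    """Raised when stimulus placement violates the design constraints."""


class SequencingError(RuntimeError):
    """Raised when the pseudorandomization constraints cannot be satisfied."""


@dataclass(frozen=True)
class Stimulus:
    label: str
    rho: float
    role: Role
    adjacent_cs_plus: str = ""

    def __post_init__(self):
        if not 0.0 < self.rho < 1.0:
            raise InvalidDesignError(
                f"stimulus {self.label!r}: rho={self.rho} outside (0, 1)"
            )
        if self.role is Role.GS and not self.adjacent_cs_plus:
            raise InvalidDesignError(
                f"GS {self.label!r} must name its adjacent CS+"
            )
        if self.role is not Role.GS and self.adjacent_cs_plus:
            raise InvalidDesignError(
                f"non-GS {self.label!r} cannot have an adjacent CS+"
            )


@dataclass(frozen=True)
class TaskDesign:
    """Stimulus array plus schedule constants of the avoidance task."""

    stimuli: tuple[Stimulus, ...]
    theta: float
    reinforcement_rate: float = 0.80
    avoid_cost: float = 0.20
    trials_per_block_by_role: dict = field(
        default_factory=lambda: {Role.CS_MINUS: 10, Role.CS_PLUS: 10, Role.GS: 2}
    )
    n_blocks: int = 5

    def __post_init__(self):
        if not 0.0 <= self.reinforcement_rate <= 1.0:
            raise InvalidDesignError("reinforcement_rate outside [0, 1]")
        if self.avoid_cost < 0:
            raise InvalidDesignError("avoid_cost must be >= 0")
        rhos = sorted(s.rho for s in self.stimuli)
        for a, b in zip(rhos, rhos[1:]):
            if b - a < 1e-6:
                raise InvalidDesignError(
                    f"overlapping stimuli: rho {a} and {b} closer than 1e-6"
                )
        labels = {s.label for s in self.stimuli}
        for s in self.stimuli:
            if s.role is Role.GS and s.adjacent_cs_plus not in labels:
                raise InvalidDesignError(
                    f"GS {s.label!r} names unknown CS+ {s.adjacent_cs_plus!r}"
                )

    # -- lookups -----------------------------------------------------------
    def stimulus(self, label: str) -> Stimulus:
        for s in self.stimuli:
            if s.label == label:
                return s
        raise KeyError(label)

    def by_role(self, role: Role) -> list[Stimulus]:
        return [s for s in self.stimuli if s.role is role]

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.stimuli]

    @property
    def rho(self) -> np.ndarray:
        return np.array([s.rho for s in self.stimuli])

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def trials_per_block(self) -> int:
        return sum(
            self.trials_per_block_by_role[s.role] for s in self.stimuli
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "stimuli": [
                    {
                        "label": s.label,
                        "rho": s.rho,
                        "role": s.role.value,
                        "adjacent_cs_plus": s.adjacent_cs_plus,
                    }
                    for s in self.stimuli
                ],
                "theta": self.theta,
                "reinforcement_rate": self.reinforcement_rate,
                "avoid_cost": self.avoid_cost,
                "trials_per_block_by_role": {
                    r.value: n for r, n in self.trials_per_block_by_role.items()
                },
                "n_blocks": self.n_blocks,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TaskDesign":
        d = json.loads(text)
        stimuli = tuple(
            Stimulus(s["label"], s["rho"], Role(s["role"]), s["adjacent_cs_plus"])
            for s in d["stimuli"]
        )
        return cls(
            stimuli=stimuli,
            theta=d["theta"],
            reinforcement_rate=d["reinforcement_rate"],
            avoid_cost=d["avoid_cost"],
            trials_per_block_by_role={
                Role(r): n for r, n in d["trials_per_block_by_role"].items()
            },
            n_blocks=d["n_blocks"],
        )


@dataclass(frozen=True)
class TrialSequence:
    """Ordered trials with the outcome each would deliver if not avoided."""

    design: TaskDesign
    block: np.ndarray       # int, 0-based block index
    stimulus: np.ndarray    # int, index into design.stimuli
    scheduled_outcome: np.ndarray  # 0 (neutral) or -1 (aversive), if unavoided
    seed: int

    def __len__(self) -> int:
        return len(self.block)

    def to_frame(self, subject_id: str = "sub-01") -> pd.DataFrame:
        labels = self.design.labels
        return pd.DataFrame(
            {
                "subject_id": subject_id,
                "block": self.block + 1,
                "trial": np.arange(1, len(self) + 1),
                "stimulus": [labels[i] for i in self.stimulus],
                "role": [self.design.stimuli[i].role.value for i in self.stimulus],
                "rho": [self.design.stimuli[i].rho for i in self.stimulus],
                "scheduled_outcome": self.scheduled_outcome,
            }
        )


def build_design(
    theta: float = THETA_FMRI,
    cs_minus_rho: float = 0.40,
    axis_flipped: bool = False,
    reinforcement_rate: float = 0.80,
    avoid_cost: float = 0.20,
    n_blocks: int = 5,
) -> TaskDesign:
    """Place the 7-stimulus array on the spikiness axis.

    CS+ sit at rho 0.25 and 0.75; each is flanked by two GS at ``+-theta``;
    the CS- sits at ``cs_minus_rho`` (default 0.40, i.e. nearer to the lower
    CS+). ``axis_flipped`` mirrors every coordinate about 0.5, preserving
    all pairwise distances (counterbalancing).
    """
    cs_plus_rho = (0.25, 0.75)
    if not 0 < theta < min(cs_plus_rho[0], 1 - cs_plus_rho[1]):
        raise InvalidDesignError(
            f"theta={theta} pushes a GS outside the (0, 1) axis"
        )
    if any(abs(cs_minus_rho - r) < 1e-6 for r in cs_plus_rho):
        raise InvalidDesignError("cs_minus_rho collides with a CS+")

    def place(r: float) -> float:
        return 1.0 - r if axis_flipped else r

    stimuli = []
    for k, r in enumerate(cs_plus_rho, start=1):
        stimuli.append(Stimulus(f"csp{k}", place(r), Role.CS_PLUS))
    stimuli.append(Stimulus("csm", place(cs_minus_rho), Role.CS_MINUS))
    for k, r in enumerate(cs_plus_rho, start=1):
        stimuli.append(Stimulus(f"gs{k}lo", place(r - theta), Role.GS, f"csp{k}"))
        stimuli.append(Stimulus(f"gs{k}hi", place(r + theta), Role.GS, f"csp{k}"))
    return TaskDesign(
        stimuli=tuple(stimuli),
        theta=theta,
        reinforcement_rate=reinforcement_rate,
        avoid_cost=avoid_cost,
        n_blocks=n_blocks,
    )


def amt_design(**kwargs) -> TaskDesign:
    """Design preset for the online sample (fixed theta = 0.065)."""
    kwargs.setdefault("theta", THETA_AMT)
    return build_design(**kwargs)


def _block_order(design: TaskDesign, rng: np.random.Generator,
                 first_block: bool, max_tries: int = 1000) -> list[int]:
    """One pseudorandom block honouring the GS-spacing constraints.

    Constraints (chosen to minimise learning about GS): no two GS trials
    adjacent; no GS within the first 5 trials of block 1.
    """
    items: list[int] = []
    for i, s in enumerate(design.stimuli):
        items.extend([i] * design.trials_per_block_by_role[s.role])
    is_gs = np.array([design.stimuli[i].role is Role.GS for i in items])
    items = np.asarray(items)
    for _ in range(max_tries):
        perm = rng.permutation(len(items))
        order, gs = items[perm], is_gs[perm]
        if np.any(gs[:-1] & gs[1:]):
            continue
        if first_block and np.any(gs[:5]):
            continue
        return list(order)
    raise SequencingError(
        "could not satisfy sequencing rule 'no adjacent GS trials"
        + ("; no GS in first 5 trials of block 1" if first_block else "")
        + f"' after {max_tries} shuffles"
    )


def generate_sequence(
    design: TaskDesign,
    seed: int,
    quota_reinforcement: bool = False,
) -> TrialSequence:
    """Pseudorandom trial sequence with scheduled outcomes.

    Per block: designed role counts exactly (default 10 CS-, 10 per CS+,
    2 per GS = 38 trials).  Unavoided-CS+ outcomes are independent
    Bernoulli(reinforcement_rate) draws by default; ``quota_reinforcement``
    instead enforces the exact per-block proportion (rounded) per CS+.
    """
    rng = np.random.default_rng(seed)
    blocks, stims, outcomes = [], [], []
    for b in range(design.n_blocks):
        order = _block_order(design, rng, first_block=(b == 0))
        sched = []
        if quota_reinforcement:
            per_stim: dict[int, list[int]] = {}
            for i, s in enumerate(design.stimuli):
                if s.role is Role.CS_PLUS:
                    n = design.trials_per_block_by_role[Role.CS_PLUS]
                    n_shock = int(round(design.reinforcement_rate * n))
                    outs = [AVERSIVE] * n_shock + [NEUTRAL] * (n - n_shock)
                    rng.shuffle(outs)
                    per_stim[i] = outs
            for i in order:
                if design.stimuli[i].role is Role.CS_PLUS:
                    sched.append(per_stim[i].pop())
                else:
                    sched.append(NEUTRAL)
        else:
            for i in order:
                if design.stimuli[i].role is Role.CS_PLUS:
                    sched.append(
                        AVERSIVE
                        if rng.random() < design.reinforcement_rate
                        else NEUTRAL
                    )
                else:
                    sched.append(NEUTRAL)
        blocks.extend([b] * len(order))
        stims.extend(order)
        outcomes.extend(sched)
    return TrialSequence(
        design=design,
        block=np.asarray(blocks, dtype=np.int64),
        stimulus=np.asarray(stims, dtype=np.int64),
        scheduled_outcome=np.asarray(outcomes, dtype=np.int64),
        seed=seed,
    )
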