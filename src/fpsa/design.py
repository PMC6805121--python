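"""Trial-sequence generation.

Baseline and generalization runs are built from an order-2 maximum-length
sequence (m-sequence) over the 11-symbol alphabet {8 faces, UCS, oddball,
null}.  An order-2 m-sequence over GF(11) has period 11^2 - 1 = 120; over
one period every nonzero symbol occurs exactly 11 times and the zero
symbol 10 times.  Assigning the zero symbol to the null condition and the
ten nonzero symbols to the 8 faces, UCS and oddball therefore yields a
120-trial run with 11 repetitions per face.  To reach the design's
reinforcement and oddball rates, excess UCS trials are randomly pruned
down to 5 per run and oddballs down to 1; pruned trials are relabeled as
null, giving 10 + 6 + 10 = 26 null trials per run.

The conditioning phase is not sequence-optimized: CS+ and CS- each appear
25 times, plus 11 reinforced CS+ presentations, the remainder null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import FACE_ANGLES, PipelineConfig

# Recurrence s[n] = A*s[n-1] + B*s[n-2] mod Q.  x^2 - x - 3 is primitive
# over GF(11): the state sequence cycles through all 120 nonzero pairs.
_Q = 11
_A, _B = 1, 3

#: per-run design counts for baseline/generalization runs
N_TRIALS_RUN = 120
N_UCS_RUN = 5
N_ODDBALL_RUN = 1
N_NULL_RUN = 26
N_FACE_REPS = 11

#: conditioning-phase counts
N_TRIALS_COND = 124
N_CS_REPS_COND = 25
N_REINFORCED_COND = 11


@dataclass(frozen=True)
class Trial:
    """One presentation slot of a run."""

    index: int
    condition: str          # "face_<angle>", "ucs", "oddball" or "null"
    face_angle: float | None
    onset_s: float
    reinforced: bool = False


@dataclass
class TrialSequence:
    """Ordered trials of one run, with phase/run labels and timing."""

    phase: str
    run: int
    trials: list = field(default_factory=list)
    stim_duration_s: float = 1.5

    def __len__(self):
        return len(self.trials)

    def condition_counts(self) -> dict:
        out: dict = {}
        for t in self.trials:
            out[t.condition] = out.get(t.condition, 0) + 1
        return out


def face_condition(angle) -> str:
    """Canonical condition label for a face angle."""
    return f"face_{int(angle)}"


def m_sequence(seed: int) -> np.ndarray:
    """One period (length 120) of the order-2 m-sequence over GF(11).

    The seed selects the starting state (a cyclic rotation of the fixed
    sequence), so symbol counts are seed-invariant: nonzero symbols occur
    11 times, zero 10 times.
    """
    rng = np.random.default_rng(seed)
    # random nonzero initial state
    while True:
        s0, s1 = rng.integers(0, _Q, size=2)
        if (s0, s1) != (0, 0):
            break
    seq = np.empty(N_TRIALS_RUN, dtype=np.int64)
    seq[0], seq[1] = s0, s1
    for n in range(2, N_TRIALS_RUN):
        seq[n] = (_A * seq[n - 1] + _B * seq[n - 2]) % _Q
    return seq


def generate_trial_sequence(
    phase: str,
    run: int,
    seed: int,
    config: PipelineConfig | None = None,
) -> TrialSequence:
    """Generate one run of trials for the given phase.

    Baseline and generalization runs are pruned m-sequences (see module
    docstring); the conditioning run uses a seeded random shuffle of the
    stated condition counts.  The same seed always yields the same run.

    Parameters
    ----------
    phase
        One of ``"baseline"``, ``"conditioning"``, ``"generalization"``.
    run
        Run number (>= 1); folded into the random stream.
    seed
        Base seed for the run.
    """
    if config is None:
        config = PipelineConfig()
    if phase not in ("baseline", "conditioning", "generalization"):
        raise ValueError(f"unknown phase: {phase!r}")
    rng = np.random.default_rng([seed, run, {"baseline": 0,
                                             "conditioning": 1,
                                             "generalization": 2}[phase]])

    if phase == "conditioning":
        labels = (
            ["cs_plus"] * N_CS_REPS_COND
            + ["cs_minus"] * N_CS_REPS_COND
            + ["ucs"] * N_REINFORCED_COND
        )
        labels += ["null"] * (N_TRIALS_COND - len(labels))
        rng.shuffle(labels)
        symbols = labels
    else:
        seq = m_sequence(int(rng.integers(2**31)))
        # symbol -> condition assignment: zero symbol is null; a seeded
        # permutation maps the ten nonzero symbols to faces/UCS/oddball.
        nonzero_roles = [face_condition(a) for a in FACE_ANGLES] + ["ucs", "oddball"]
        perm = rng.permutation(10)
        role_of = {0: "null"}
        for sym, k in zip(range(1, _Q), perm):
            role_of[sym] = nonzero_roles[k]
        symbols = [role_of[int(s)] for s in seq]
        # prune excess UCS / oddball occurrences into null trials
        for cond, keep in (("ucs", N_UCS_RUN), ("oddball", N_ODDBALL_RUN)):
            idx = [i for i, c in enumerate(symbols) if c == cond]
            kept = rng.choice(len(idx), size=keep, replace=False)
            for j, i in enumerate(idx):
                if j not in set(int(k) for k in kept):
                    symbols[i] = "null"

    # timing: null trials carry no stimulus and stretch the effective SOA
    trials = []
    onset = 0.0
    for i, cond in enumerate(symbols):
        angle = None
        if cond.startswith("face_"):
            angle = float(cond.split("_", 1)[1])
        reinforced = cond == "ucs"
        trials.append(
            Trial(index=i, condition=cond, face_angle=angle,
                  onset_s=onset, reinforced=reinforced)
        )
        onset += config.soa_s
    return TrialSequence(
        phase=phase,
        run=run,
        trials=trials,
        stim_duration_s=config.stim_duration_ms / 1000.0,
    )
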