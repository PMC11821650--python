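"""Q-learning model with subjective valuation of the ambiguous no-feedback outcome.

The agent maintains an expected value Q(s, a) for each of the four stimuli and
two responses, all initialized to 0.  On each trial it chooses a response by a
softmax over the two Q-values, observes the outcome, converts it to a
reinforcement value r, and updates the chosen Q by the prediction error
``pe = r - Q(s, a)`` with an asymmetric learning rate: LR+ when the outcome is
better than expected (pe > 0), LR- when worse (pe < 0).

Reinforcement is on the unit scale, not the point scale: explicit reward is
+1, explicit punishment is -1, and the ambiguous no-feedback outcome is worth
R0, a free parameter in [-1, +1].  R0 = +1 makes no-feedback equivalent to an
explicit reward, R0 = -1 to an explicit punishment, R0 = 0 truly neutral.
R0 is the model's handle on how a participant subjectively values "nothing
happened" -- the quantity of central clinical interest here.

The explore/exploit parameter beta in (0, 1) maps to a softmax temperature
``tau = beta / (1 - beta)``: beta near 0 is greedy exploitation, beta near 1
approaches uniform random choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import STIMULI, TrialSchedule, resolve_feedback, STARTING_TALLY

__all__ = [
    "AgentParams",
    "PARAM_NAMES",
    "PARAM_BOUNDS",
    "outcome_value",
    "q_update",
    "choice_probabilities",
    "negative_log_likelihood",
    "simulate_agent",
    "compile_trials",
]

#: Numerical guards: temperature kept finite, probabilities kept off 0 and 1.
TAU_MIN, TAU_MAX = 1e-3, 1e3
P_MIN = 1e-6
BETA_EPS = 1e-3

PARAM_NAMES = ("lr_plus", "lr_minus", "beta", "r0")
PARAM_BOUNDS = {
    "lr_plus": (0.0, 1.0),
    "lr_minus": (0.0, 1.0),
    "beta": (BETA_EPS, 1.0 - BETA_EPS),
    "r0": (-1.0, 1.0),
}

_STIM_INDEX = {sid: i for i, sid in enumerate(STIMULI)}
_RESP_INDEX = {"A": 0, "B": 1}
_FB_CODE = {"reward": 0, "punish": 1, "none": 2}


@dataclass(frozen=True)
class AgentParams:
    """The four latent variables of the learning model.

    Attributes
    ----------
    lr_plus : float
        Learning rate on better-than-expected outcomes, in [0, 1].
    lr_minus : float
        Learning rate on worse-than-expected outcomes, in [0, 1].
    beta : float
        Explore/exploit parameter in (0, 1); ~0 exploit, ~1 explore.
    r0 : float
        Subjective value of the ambiguous no-feedback outcome, in [-1, +1].
    """

    lr_plus: float
    lr_minus: float
    beta: float
    r0: float

    def __post_init__(self) -> None:
        for name in ("lr_plus", "lr_minus"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"beta must be in (0, 1), got {self.beta}")
        if not -1.0 <= self.r0 <= 1.0:
            raise ValueError(f"r0 must be in [-1, 1], got {self.r0}")

    def as_array(self) -> np.ndarray:
        return np.array([self.lr_plus, self.lr_minus, self.beta, self.r0])

    @classmethod
    def from_array(cls, x) -> "AgentParams":
        return cls(float(x[0]), float(x[1]), float(x[2]), float(x[3]))


def outcome_value(feedback: str, r0: float) -> float:
    """Reinforcement value of an observed outcome on the unit scale."""
    if feedback == "reward":
        return 1.0
    if feedback == "punish":
        return -1.0
    if feedback == "none":
        if not -1.0 <= r0 <= 1.0:
            raise ValueError(f"r0 must be in [-1, 1], got {r0}")
        return float(r0)
    raise ValueError(f"unknown feedback {feedback!r}")


def q_update(q_sa: float, r: float, lr_plus: float, lr_minus: float) -> float:
    """Prediction-error update of the chosen Q-value.

    pe = r - q_sa; positive pe steps by lr_plus, negative by lr_minus, zero pe
    leaves q unchanged (either rate would give the same result).
    """
    pe = r - q_sa
    if pe > 0:
        return q_sa + lr_plus * pe
    if pe < 0:
        return q_sa + lr_minus * pe
    return q_sa


def _tau(beta: float) -> float:
    return min(max(beta / (1.0 - beta), TAU_MIN), TAU_MAX)


def choice_probabilities(q_a: float, q_b: float, beta: float) -> tuple[float, float]:
    """Softmax choice probabilities for the two responses.

    Temperature is tau = beta/(1-beta), clamped to [1e-3, 1e3]; probabilities
    are clamped to [1e-6, 1 - 1e-6].  Computed overflow-safely from the
    Q-value difference.
    """
    d = (q_a - q_b) / _tau(beta)
    if d >= 0:
        p_a = 1.0 / (1.0 + math.exp(-d))
    else:
        e = math.exp(d)
        p_a = e / (1.0 + e)
    p_a = min(max(p_a, P_MIN), 1.0 - P_MIN)
    return p_a, 1.0 - p_a


def compile_trials(trials: pd.DataFrame) -> tuple[list[int], list[int], list[int]]:
    """Flatten a cleaned trial log into index lists for the likelihood loop.

    Returns (stimulus index 0-3, response index 0/1, feedback code 0/1/2) in
    trial order.  Practice rows must already be removed.
    """
    if len(trials) == 0:
        raise ValueError("empty trial list")
    df = trials.sort_values("trial_index")
    try:
        stim = [_STIM_INDEX[s] for s in df["stimulus_id"]]
        resp = [_RESP_INDEX[r] for r in df["response"]]
        fb = [_FB_CODE[f] for f in df["feedback"]]
    except KeyError as exc:  # unknown enum value
        raise ValueError(f"unknown enumeration value {exc.args[0]!r} in trial log")
    return stim, resp, fb


def _nll_core(
    stim: list[int],
    resp: list[int],
    fb: list[int],
    lr_plus: float,
    lr_minus: float,
    beta: float,
    r0: float,
) -> float:
    # Hot path: called thousands of times per session fit.  Plain-float loop
    # beats numpy here because trials are sequentially dependent.
    tau = min(max(beta / (1.0 - beta), TAU_MIN), TAU_MAX)
    q = [0.0] * 8
    nll = 0.0
    exp = math.exp
    log = math.log
    for i in range(len(stim)):
        s2 = 2 * stim[i]
        a = resp[i]
        d = (q[s2] - q[s2 + 1]) / tau
        if d >= 0:
            p_a = 1.0 / (1.0 + exp(-d))
        else:
            e = exp(d)
            p_a = e / (1.0 + e)
        p = p_a if a == 0 else 1.0 - p_a
        if p < P_MIN:
            p = P_MIN
        elif p > 1.0 - P_MIN:
            p = 1.0 - P_MIN
        nll -= log(p)
        f = fb[i]
        r = 1.0 if f == 0 else (-1.0 if f == 1 else r0)
        qa = q[s2 + a]
        pe = r - qa
        if pe > 0.0:
            q[s2 + a] = qa + lr_plus * pe
        elif pe < 0.0:
            q[s2 + a] = qa + lr_minus * pe
    if not math.isfinite(nll):
        raise FloatingPointError("non-finite negative log-likelihood")
    return nll


def negative_log_likelihood(trials: pd.DataFrame, params: AgentParams) -> float:
    """Negative log-likelihood (natural log) of observed choices under the model.

    Trials are processed in trial_index order: on each trial the choice
    probability under the current Q state is accumulated as ``-ln p(response)``,
    the recorded feedback is mapped through :func:`outcome_value`, and the
    chosen Q-value is updated.  Deterministic for fixed inputs; raises on an
    empty trial list.
    """
    stim, resp, fb = compile_trials(trials)
    return _nll_core(
        stim, resp, fb, params.lr_plus, params.lr_minus, params.beta, params.r0
    )


def simulate_agent(
    schedule: TrialSchedule,
    params: AgentParams,
    seed: int,
    session_id: str = "sim",
    subject_id: str = "sim-subject",
    include_practice: bool = False,
) -> pd.DataFrame:
    """Run a model agent through a schedule and return a trial log.

    Responses are sampled from the softmax choice probabilities; feedback is
    resolved by the task environment using the schedule's assigned categories.
    Reaction times are drawn from a lognormal (median ~800 ms, all >= 200 ms)
    purely to populate the log format -- the model does not describe RTs.
    Reproducible under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    tally = STARTING_TALLY
    if include_practice:
        rows.extend(_practice_rows(session_id, subject_id))
        tally = rows[-1]["tally_after"]
    q = np.zeros((4, 2))
    for t in schedule.trials:
        s = _STIM_INDEX[t.stimulus_id]
        p_a, _ = choice_probabilities(q[s, 0], q[s, 1], params.beta)
        a = 0 if rng.random() < p_a else 1
        response = "A" if a == 0 else "B"
        out = resolve_feedback(t, response)
        tally += out.tally_delta
        r = outcome_value(out.feedback, params.r0)
        q[s, a] = q_update(q[s, a], r, params.lr_plus, params.lr_minus)
        rt = max(200.0, float(rng.lognormal(mean=math.log(800.0), sigma=0.35)))
        rows.append(
            {
                "session_id": session_id,
                "subject_id": subject_id,
                "trial_index": t.trial_index,
                "block": t.block,
                "practice_flag": False,
                "stimulus_id": t.stimulus_id,
                "valence": t.valence,
                "assigned_category": t.assigned_category,
                "response": response,
                "correct": out.correct,
                "feedback": out.feedback,
                "tally_after": tally,
                "rt_ms": round(rt, 1),
            }
        )
    return pd.DataFrame(rows)


def _practice_rows(session_id: str, subject_id: str) -> list[dict]:
    """Guided practice prefix: two extra stimuli, four scripted trials.

    One rewarded and one unrewarded trial on a reward-valenced practice
    stimulus, one punished and one feedback-free trial on a punishment-valenced
    one.  Flagged practice=True and excluded from all scoring and fitting.
    """
    plan = [
        ("P1", "reward", "A", "A", True, "reward", 25),
        ("P1", "reward", "B", "A", False, "none", 0),
        ("P2", "punishment", "A", "B", False, "punish", -25),
        ("P2", "punishment", "A", "A", True, "none", 0),
    ]
    rows = []
    tally = STARTING_TALLY
    for i, (sid, valence, assigned, response, correct, feedback, delta) in enumerate(
        plan
    ):
        tally += delta
        rows.append(
            {
                "session_id": session_id,
                "subject_id": subject_id,
                "trial_index": -(len(plan) - i),  # practice indexed ..,-2,-1
                "block": 0,
                "practice_flag": True,
                "stimulus_id": sid,
                "valence": valence,
                "assigned_category": assigned,
                "response": response,
                "correct": correct,
                "feedback": feedback,
                "tally_after": tally,
                "rt_ms": 800.0,
            }
        )
    return rows
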