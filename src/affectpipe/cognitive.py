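"""Scoring of the three cognitive tasks into 18 outcome measures.

Recognition memory is scored with equal-variance signal detection theory
(d' and criterion C per word valence), situation construal with normalized
ratings and reaction times per image valence, and the word find with
average find order and average find time per word valence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SDTScores",
    "score_recognition",
    "score_construal",
    "score_word_find",
    "score_all",
]

_VALENCES = ("pos", "neg", "neu")


@dataclass
class SDTScores:
    """Signal-detection scores for one valence cell.

    ``d_prime = z(H) - z(F)`` and ``c = -(z(H) + z(F)) / 2`` with ``z`` the
    probit (inverse normal CDF). Positive ``c`` means a conservative bias
    toward responding "new". ``hit_rate`` / ``fa_rate`` are the rates after
    extreme-rate correction.
    """

    valence: str
    hit_rate: float
    fa_rate: float
    d_prime: float
    c: float


def _corrected_rate(k: int, n: int) -> float:
    """Rate with 0 -> 1/(2N) and 1 -> 1 - 1/(2N) boundary correction."""
    r = k / n
    if r <= 0.0:
        return 1.0 / (2 * n)
    if r >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    return r


def score_recognition(
    log: pd.DataFrame,
    n_per_cell: int = 16,
    edge_rule: str = "rate",
) -> list[SDTScores]:
    """Score one participant-session recognition log per valence.

    Parameters
    ----------
    log : frame with columns valence, is_old, clicked (one row per word).
    n_per_cell : old (and new) words per valence; sets the 1/(2N) boundary.
    edge_rule : ``"rate"`` (default) applies the boundary correction to the
        hit/false-alarm rate before the probit transform; ``"dprime"``
        instead sets d' itself to 1/(2N) (rate 0) or 1 - 1/(2N) (rate 1)
        when either rate is extreme.
    """
    if edge_rule not in ("rate", "dprime"):
        raise ValueError(f"unknown edge_rule {edge_rule!r}")
    out = []
    for v in _VALENCES:
        cell = log[log["valence"] == v]
        old = cell[cell["is_old"].astype(bool)]
        new = cell[~cell["is_old"].astype(bool)]
        if old.empty or new.empty:
            raise ValueError(f"recognition log has an empty cell for valence {v!r}")
        n_old, n_new = len(old), len(new)
        hits = int(old["clicked"].sum())
        fas = int(new["clicked"].sum())
        raw_h, raw_f = hits / n_old, fas / n_new
        H = _corrected_rate(hits, n_old)
        F = _corrected_rate(fas, n_new)
        extreme = raw_h in (0.0, 1.0) or raw_f in (0.0, 1.0)
        if edge_rule == "dprime" and extreme:
            d = (1.0 / (2 * n_per_cell)) if (raw_h == 0.0 or raw_f == 0.0) else (
                1.0 - 1.0 / (2 * n_per_cell)
            )
            c = -(norm.ppf(H) + norm.ppf(F)) / 2.0
        else:
            d = float(norm.ppf(H) - norm.ppf(F))
            c = float(-(norm.ppf(H) + norm.ppf(F)) / 2.0)
        out.append(SDTScores(valence=v, hit_rate=H, fa_rate=F, d_prime=d, c=c))
    return out


def score_construal(log: pd.DataFrame) -> pd.DataFrame:
    """Per image valence: mean normalized response and mean reaction time.

    Ratings 1-7 are mapped linearly to [-1, 1] via (r - 4) / 3;
    negative-polarity items are sign-flipped so positive values always mean
    a more positive appraisal of the situation.
    """
    ratings = log["rating"].to_numpy()
    if ratings.min() < 1 or ratings.max() > 7:
        raise ValueError("construal ratings must lie in 1..7")
    if (log["reaction_time_s"] <= 0).any():
        raise ValueError("reaction times must be positive")
    normalized = (ratings - 4.0) / 3.0
    flip = np.where(log["item_polarity"].to_numpy() == "negative", -1.0, 1.0)
    scored = log.assign(response_normalized=normalized * flip)
    return (
        scored.groupby("image_valence")
        .agg(
            response_normalized=("response_normalized", "mean"),
            mean_reaction_time=("reaction_time_s", "mean"),
        )
        .reset_index()
    )


def score_word_find(log: pd.DataFrame, mode: str = "strict") -> pd.DataFrame:
    """Per word valence: average find order (1..9) and average find time (ms).

    In ``strict`` mode a log missing any of the nine words raises an error
    listing them; in ``lenient`` mode valence groups touched by missing
    words score NaN and a ``complete`` flag marks the remainder.
    """
    orders = sorted(log["find_order"].tolist())
    missing = sorted(set(range(1, 10)) - set(orders))
    if missing or len(log) != 9:
        if mode == "strict":
            raise ValueError(f"word-find log incomplete; missing find orders {missing}")
    elif orders != list(range(1, 10)):
        raise ValueError("find orders must be a permutation of 1..9")
    out = (
        log.groupby("valence")
        .agg(
            average_order=("find_order", "mean"),
            average_find_time=("find_time_ms", "mean"),
        )
        .reset_index()
    )
    out["complete"] = not missing and len(log) == 9
    if missing:
        out[["average_order", "average_find_time"]] = np.nan
    return out


_KEY = {"pos": "Pos", "neg": "Neg", "neu": "Neu", "ambiguous": "Amb"}


def score_all(logs: dict[str, pd.DataFrame], edge_rule: str = "rate") -> pd.DataFrame:
    """Score every participant/session into the 18-column measure table.

    ``logs`` is the dict produced by ``synthetic.simulate_cognitive_logs``
    (or logs read from CSV with the same schemas). Output is indexed by
    (participant_id, session).
    """
    rows: dict[tuple, dict] = {}

    for (pid, sess), g in logs["recognition"].groupby(["participant_id", "session"]):
        row = rows.setdefault((pid, sess), {})
        for s in score_recognition(g, edge_rule=edge_rule):
            row[f"{_KEY[s.valence]} d-prime"] = s.d_prime
            row[f"{_KEY[s.valence]} c"] = s.c

    for (pid, sess), g in logs["construal"].groupby(["participant_id", "session"]):
        row = rows.setdefault((pid, sess), {})
        for _, r in score_construal(g).iterrows():
            key = _KEY[r["image_valence"]]
            row[f"Response Normalized {key}"] = r["response_normalized"]
            row[f"Response Time {key}"] = r["mean_reaction_time"]

    for (pid, sess), g in logs["word_find"].groupby(["participant_id", "session"]):
        row = rows.setdefault((pid, sess), {})
        for _, r in score_word_find(g).iterrows():
            key = _KEY[r["valence"]]
            row[f"Order {key}"] = r["average_order"]
            row[f"Find Time {key}"] = r["average_find_time"]

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["participant_id", "session"])
    return table.sort_index()
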