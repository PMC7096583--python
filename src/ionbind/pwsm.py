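"""Position-weight scoring matrices (PWSM) and the 5*2L feature vector.

For one channel with alphabet size K and window length L, the
position-specific occurrence probability of symbol j at window position i is

    P_ij = (n_ij + N_i / K) / (N_i + N_i)

where n_ij counts symbol j at position i over the training segments and N_i
is the total number of segments.  This is an equal-weight mixture of the
empirical frequency and the uniform distribution, so every row sums to one
and every entry is strictly positive.  The weight matrix is the log-odds
against a background distribution:

    W_ij = ln(P_ij / P_oj)

One matrix pair is fit per channel: P/W from the positive training set and
from the negative training set.  Scoring a segment looks up, per channel,
its L symbols in the positive weight matrix (features 1..L) and in the
negative weight matrix (features L+1..2L), giving 2L values per channel and
5*2L = 10L values in total, named WA1..WA2L, QS1..QS2L, DH1..DH2L,
SS1..SS2L, SA1..SA2L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channels import CHANNELS, channel_alphabets
from .core import LigandProfile

BACKGROUND_MODES = ("pooled", "uniform")


def _count_matrix(strings: list[str], alphabet: str) -> np.ndarray:
    L = len(strings[0])
    index = {sym: j for j, sym in enumerate(alphabet)}
    counts = np.zeros((L, len(alphabet)), dtype=float)
    for s in strings:
        if len(s) != L:
            raise ValueError(f"segment string length {len(s)} != expected {L}")
        for i, sym in enumerate(s):
            try:
                counts[i, index[sym]] += 1
            except KeyError:
                raise ValueError(
                    f"symbol {sym!r} not in alphabet {alphabet!r}"
                ) from None
    return counts


def build_probability_matrix(strings: list[str], alphabet: str) -> np.ndarray:
    """L x K matrix of mixture-smoothed position-specific symbol probabilities."""
    if not strings:
        raise ValueError("cannot build a probability matrix from an empty training set")
    counts = _count_matrix(strings, alphabet)
    K = len(alphabet)
    N = counts.sum(axis=1, keepdims=True)  # == len(strings) at every position
    return (counts + N / K) / (2.0 * N)


def build_weight_matrix(P: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Elementwise log-odds W_ij = ln(P_ij / P_oj)."""
    background = np.asarray(background, dtype=float)
    if np.any(background <= 0):
        raise ValueError("background probabilities must all be positive")
    if np.any(P <= 0):
        raise ValueError("probability matrix entries must all be positive")
    return np.log(P / background[np.newaxis, :])


def pooled_background(
    pos_strings: list[str], neg_strings: list[str], alphabet: str
) -> np.ndarray:
    """Symbol frequencies pooled over every position of both training sets,
    with the same uniform-mixture smoothing as the probability matrices."""
    counts = (
        _count_matrix(pos_strings, alphabet).sum(axis=0)
        + _count_matrix(neg_strings, alphabet).sum(axis=0)
    )
    N = counts.sum()
    return (counts + N / len(alphabet)) / (2.0 * N)


@dataclass
class PWSMPair:
    """Positive- and negative-class probability and weight matrices for one
    channel at one window length."""

    channel: str
    alphabet: str
    P_pos: np.ndarray
    P_neg: np.ndarray
    W_pos: np.ndarray
    W_neg: np.ndarray
    background: np.ndarray

    @property
    def L(self) -> int:
        return self.P_pos.shape[0]

    @property
    def K(self) -> int:
        return len(self.alphabet)


def fit_pwsm_pair(
    pos_strings: list[str],
    neg_strings: list[str],
    alphabet: str,
    channel: str = "",
    background: str = "pooled",
) -> PWSMPair:
    """Fit the positive/negative matrix pair for one channel.

    ``background='pooled'`` (default) uses the smoothed symbol frequency over
    all training segments of both classes; ``'uniform'`` uses 1/K.
    """
    if not pos_strings or not neg_strings:
        raise ValueError("both positive and negative training sets must be non-empty")
    if background not in BACKGROUND_MODES:
        raise ValueError(f"unknown background mode {background!r}")
    P_pos = build_probability_matrix(pos_strings, alphabet)
    P_neg = build_probability_matrix(neg_strings, alphabet)
    if P_pos.shape != P_neg.shape:
        raise ValueError("positive and negative segments have different lengths")
    if background == "uniform":
        bg = np.full(len(alphabet), 1.0 / len(alphabet))
    else:
        bg = pooled_background(pos_strings, neg_strings, alphabet)
    return PWSMPair(
        channel=channel,
        alphabet=alphabet,
        P_pos=P_pos,
        P_neg=P_neg,
        W_pos=build_weight_matrix(P_pos, bg),
        W_neg=build_weight_matrix(P_neg, bg),
        background=bg,
    )


def fit_all_pairs(
    encoded_pos: list[tuple[str, ...]],
    encoded_neg: list[tuple[str, ...]],
    profile: LigandProfile,
    background: str = "pooled",
) -> dict[str, PWSMPair]:
    """Fit one PWSMPair per channel from encoded training segments."""
    alphabets = channel_alphabets(profile)
    pairs = {}
    for c, name in enumerate(CHANNELS):
        pairs[name] = fit_pwsm_pair(
            [e[c] for e in encoded_pos],
            [e[c] for e in encoded_neg],
            alphabets[name],
            channel=name,
            background=background,
        )
    return pairs


def feature_names(L: int) -> list[str]:
    """WA1..WA2L, QS1..QS2L, DH1..DH2L, SS1..SS2L, SA1..SA2L."""
    return [f"{ch}{t}" for ch in CHANNELS for t in range(1, 2 * L + 1)]


def score_segment(
    strings: tuple[str, ...], pairs: dict[str, PWSMPair]
) -> np.ndarray:
    """The 10L-dimensional feature vector of one encoded segment.

    Per channel, features 1..L are the positive-matrix lookups W_pos[i, s_i]
    and features L+1..2L the negative-matrix lookups W_neg[i, s_i].
    """
    values: list[float] = []
    for c, name in enumerate(CHANNELS):
        pair = pairs[name]
        s = strings[c]
        if len(s) != pair.L:
            raise ValueError(
                f"channel {name}: segment length {len(s)} != matrix length {pair.L}"
            )
        idx = {sym: j for j, sym in enumerate(pair.alphabet)}
        try:
            cols = [idx[sym] for sym in s]
        except KeyError as exc:
            raise ValueError(f"channel {name}: symbol outside alphabet") from exc
        rows = np.arange(pair.L)
        values.extend(pair.W_pos[rows, cols])
        values.extend(pair.W_neg[rows, cols])
    return np.asarray(values)


def score_matrix(
    encoded: list[tuple[str, ...]], pairs: dict[str, PWSMPair]
) -> pd.DataFrame:
    """Feature matrix (rows = segments) with named columns."""
    L = pairs[CHANNELS[0]].L
    data = np.vstack([score_segment(e, pairs) for e in encoded])
    return pd.DataFrame(data, columns=feature_names(L))


def pair_to_frame(pair: PWSMPair) -> pd.DataFrame:
    """Serialize a PWSMPair to a long-format table (for the model bundle)."""
    blocks = []
    for name, M in (
        ("P_pos", pair.P_pos), ("P_neg", pair.P_neg),
        ("W_pos", pair.W_pos), ("W_neg", pair.W_neg),
    ):
        df = pd.DataFrame(M, columns=list(pair.alphabet))
        df.insert(0, "position", np.arange(1, pair.L + 1))
        df.insert(0, "matrix", name)
        df.insert(0, "channel", pair.channel)
        blocks.append(df)
    return pd.concat(blocks, ignore_index=True)
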