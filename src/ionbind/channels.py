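"""The five per-residue feature channels and RSA discretization.

Each window is encoded as five symbol strings over finite alphabets:

* ``WA`` — amino-acid identity (20 letters + vacancy 'X');
* ``QS`` — six hydrophilicity/hydrophobicity categories;
* ``DH`` — three charge categories (positive / negative / uncharged);
* ``SS`` — three-state secondary structure (H / E / C);
* ``SA`` — discretized relative solvent accessibility under one of four
  schemes:

  - ``SA_2``: Boolean buried/exposed at the 0.25 threshold;
  - ``SA_4``: the prior four regions [0,0.2], (0.2,0.45], (0.45,0.6],
    (0.6,0.85] (E/F/G/H);
  - ``SA_V``: distribution-derived regions [0,0.15), [0.15,0.25),
    [0.25,0.35), [0.35,0.85] (A/B/C/D);
  - ``SA_P``: peak-derived regions [0,0.15), [0.15,0.4), [0.4,0.5),
    [0.5,0.85] (I/K/L/M).

PAD window positions map to a dedicated PAD symbol in every channel ('X'
for WA, 'x' elsewhere), closing each alphabet.  RSA values above 0.85 are
clamped to 0.85 with a logged warning (never silently).
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .core import AA_ALPHABET, RSA_CEILING, RSA_SCHEMES, LigandProfile, SS_STATES
from .windows import Segment

logger = logging.getLogger(__name__)

CHANNELS = ("WA", "QS", "DH", "SS", "SA")

#: PAD symbol per channel ('X' doubles as the amino-acid vacancy).
PAD_SYMBOLS = {"WA": "X", "QS": "x", "DH": "x", "SS": "x", "SA": "x"}

#: Symbols of each four-region scheme, in ascending-RSA order.
SA_SYMBOLS = {"SA_2": "be", "SA_4": "EFGH", "SA_V": "ABCD", "SA_P": "IKLM"}

#: Default interior breakpoints of the RSA schemes (overridable per ligand).
DEFAULT_SA_EDGES = {
    "SA_2": [0.25],
    "SA_4": [0.2, 0.45, 0.6],
    "SA_V": [0.15, 0.25, 0.35],
    "SA_P": [0.15, 0.4, 0.5],
}


def sa_alphabet(scheme_id: str) -> str:
    """Symbols of one RSA scheme, without the PAD symbol."""
    if scheme_id not in RSA_SCHEMES:
        raise ValueError(f"unknown RSA scheme {scheme_id!r}")
    return SA_SYMBOLS[scheme_id]


def rsa_bin(
    value: float, scheme_id: str, edges: dict[str, list[float]] | None = None
) -> str:
    """Discretize one RSA value under the given scheme.

    ``SA_V`` and ``SA_P`` use left-closed/right-open intervals (last interval
    closed at 0.85); ``SA_4`` uses left-open/right-closed intervals (first
    closed at 0); ``SA_2`` assigns exactly 0.25 to exposed.  Values above
    0.85 are clamped down to 0.85.
    """
    if value is None or not math.isfinite(value):
        raise ValueError(f"RSA value must be finite, got {value!r}")
    if value < 0:
        raise ValueError(f"RSA value must be non-negative, got {value}")
    if value > RSA_CEILING:
        logger.debug("RSA value %.4f clamped to %.2f", value, RSA_CEILING)
        value = RSA_CEILING
    cuts = DEFAULT_SA_EDGES[scheme_id] if edges is None else edges.get(
        scheme_id, DEFAULT_SA_EDGES[scheme_id]
    )
    symbols = sa_alphabet(scheme_id)
    if len(cuts) != len(symbols) - 1:
        raise ValueError(
            f"{scheme_id}: expected {len(symbols) - 1} interior breakpoints, "
            f"got {len(cuts)}"
        )
    if scheme_id == "SA_2":
        return "b" if value < cuts[0] else "e"
    if scheme_id == "SA_4":
        # [0, c0], (c0, c1], (c1, c2], (c2, 0.85]
        for cut, sym in zip(cuts, symbols):
            if value <= cut:
                return sym
        return symbols[-1]
    # SA_V / SA_P: [0, c0), [c0, c1), [c1, c2), [c2, 0.85]
    for cut, sym in zip(cuts, symbols):
        if value < cut:
            return sym
    return symbols[-1]


def channel_alphabets(profile: LigandProfile) -> dict[str, str]:
    """Ordered alphabet (including PAD symbol) per channel for a profile."""
    qs_cats = sorted(set(profile.hydrophobicity_map.values()))
    dh_cats = sorted(set(profile.charge_map.values()))
    return {
        "WA": AA_ALPHABET,  # 'X' is both vacancy and PAD
        "QS": "".join(qs_cats) + PAD_SYMBOLS["QS"],
        "DH": "".join(dh_cats) + PAD_SYMBOLS["DH"],
        "SS": SS_STATES + PAD_SYMBOLS["SS"],
        "SA": sa_alphabet(profile.rsa_scheme) + PAD_SYMBOLS["SA"],
    }


def encode_segment(segment: Segment, profile: LigandProfile) -> tuple[str, ...]:
    """Encode one segment into the five channel strings (WA, QS, DH, SS, SA).

    PAD positions yield PAD symbols in every channel; an in-chain 'X'
    residue (unknown amino acid) likewise falls back to the vacancy/PAD
    symbol in the derived channels, since no category is defined for it.
    """
    wa, qs, dh, ss, sa = [], [], [], [], []
    for r in segment.residues:
        if r.is_pad:
            wa.append("X")
            qs.append(PAD_SYMBOLS["QS"])
            dh.append(PAD_SYMBOLS["DH"])
            ss.append(PAD_SYMBOLS["SS"])
            sa.append(PAD_SYMBOLS["SA"])
            continue
        wa.append(r.aa)
        if r.aa == "X":
            qs.append(PAD_SYMBOLS["QS"])
            dh.append(PAD_SYMBOLS["DH"])
        else:
            try:
                qs.append(profile.hydrophobicity_map[r.aa])
                dh.append(profile.charge_map[r.aa])
            except KeyError as exc:
                raise ValueError(
                    f"residue {r.aa!r} missing from category map"
                ) from exc
        ss.append(r.ss)
        sa.append(rsa_bin(r.rsa, profile.rsa_scheme, profile.sa_edges))
    return ("".join(wa), "".join(qs), "".join(dh), "".join(ss), "".join(sa))


def encode_segments(
    segments: list[Segment], profile: LigandProfile
) -> list[tuple[str, ...]]:
    n_clamped = sum(
        1
        for s in segments
        for r in s.residues
        if not r.is_pad and r.rsa is not None and r.rsa > RSA_CEILING
    )
    if n_clamped:
        logger.warning(
            "%d RSA value(s) above %.2f clamped during encoding of %d segments",
            n_clamped, RSA_CEILING, len(segments),
        )
    return [encode_segment(s, profile) for s in segments]


def rsa_distribution(
    segments: list[Segment], bin_width: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram center-residue RSA values, split by binding label.

    Returns ``(bin_edges, positive_counts, negative_counts)``; counts sum to
    the number of positive/negative segments respectively.  This is the
    class-conditional RSA distribution whose separation motivates per-ligand
    RSA reclassification.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, edges[-1] + bin_width)
    pos = [s.center.rsa for s in segments if s.label == 1]
    neg = [s.center.rsa for s in segments if s.label == 0]
    pos_counts, _ = np.histogram(np.clip(pos, 0.0, edges[-1]), bins=edges)
    neg_counts, _ = np.histogram(np.clip(neg, 0.0, edges[-1]), bins=edges)
    return edges, pos_counts, neg_counts
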