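"""Sliding-window segmentation of annotated chains.

Each residue becomes the center of one length-L window; (L-1)/2 dummy 'X'
residues are appended at both chain terminals so terminal residues get full
windows.  A window whose center residue binds the ligand is a positive
sample, otherwise a negative sample.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import AnnotatedChain, PAD_RESIDUE, Residue


@dataclass(frozen=True)
class Segment:
    """A length-L window of residues centered on one chain position."""

    chain_id: str
    center_pos: int  # 0-based index in the unpadded chain
    residues: tuple[Residue, ...]
    label: int

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def center(self) -> Residue:
        return self.residues[len(self.residues) // 2]


def pad_chain(chain: AnnotatedChain, L: int) -> list[Residue]:
    """Append (L-1)/2 PAD residues at both terminals."""
    if L < 1 or L % 2 == 0:
        raise ValueError(f"window length must be a positive odd integer, got {L}")
    flank = [PAD_RESIDUE] * ((L - 1) // 2)
    return flank + list(chain.residues) + flank


def extract_segments(chain: AnnotatedChain, L: int) -> list[Segment]:
    """One overlapping window per residue, in chain order, labelled by the
    center residue's binding flag."""
    padded = pad_chain(chain, L)
    return [
        Segment(
            chain_id=chain.chain_id,
            center_pos=k,
            residues=tuple(padded[k : k + L]),
            label=chain.residues[k].label,
        )
        for k in range(len(chain))
    ]


def corpus_segments(chains: list[AnnotatedChain], L: int) -> list[Segment]:
    return [seg for chain in chains for seg in extract_segments(chain, L)]


def split_by_label(segments: list[Segment]) -> tuple[list[Segment], list[Segment]]:
    """Partition segments into (positives, negatives)."""
    pos = [s for s in segments if s.label == 1]
    neg = [s for s in segments if s.label == 0]
    return pos, neg
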