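"""Readers and writers for FASTA, the per-residue annotation table, and the
YAML configuration file.

The annotation table is a TSV with header ``chain_id  pos  aa  ss  rsa
label``; positions are 1-based in files and 0-based in memory.  Non-standard
amino-acid letters (B, J, O, U, Z, ...) are mapped to the vacancy symbol 'X'
on input so that the in-memory alphabet is closed.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .core import AA20, AnnotatedChain, LigandProfile, Residue, SS_STATES

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["chain_id", "pos", "aa", "ss", "rsa", "label"]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(chain_id, sequence)`` pairs.

    Sequences are uppercased; letters outside the 20 standard amino acids
    are replaced by 'X' with a logged warning.  Duplicate headers and empty
    files are hard errors.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate chain id {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq).upper()
        cleaned = "".join(c if c in AA20 else "X" for c in raw)
        n_sub = sum(1 for a, b in zip(raw, cleaned) if a != b)
        if n_sub:
            logger.warning(
                "%s: chain %r: %d non-standard letter(s) mapped to 'X'",
                path, rec.id, n_sub,
            )
        records.append((rec.id, cleaned))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_annotations(
    path: str | Path, chains: list[tuple[str, str]]
) -> list[AnnotatedChain]:
    """Join the annotation TSV onto FASTA chains, validating full coverage.

    Every chain must be covered by exactly one row per position, the
    annotation amino acid must match the FASTA letter, ss must be one of
    H/E/C, rsa must be a finite number and label binary.  Violations raise
    ``ValueError`` naming the chain and position.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chain_id": str, "aa": str, "ss": str})
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing column(s) {missing_cols}")
    grouped = {cid: g for cid, g in df.groupby("chain_id")}

    out: list[AnnotatedChain] = []
    for chain_id, seq in chains:
        if chain_id not in grouped:
            raise ValueError(f"{path}: no annotation rows for chain {chain_id!r}")
        g = grouped[chain_id].set_index("pos")
        for pos in range(1, len(seq) + 1):
            if pos not in g.index:
                raise ValueError(
                    f"{path}: chain {chain_id!r} position {pos} has no annotation row"
                )
        if len(g) != len(seq):
            extra = sorted(set(g.index) - set(range(1, len(seq) + 1)))
            raise ValueError(
                f"{path}: chain {chain_id!r} has unexpected positions {extra[:5]}"
            )
        residues = []
        for pos in range(1, len(seq) + 1):
            row = g.loc[pos]
            aa, ss = row["aa"], row["ss"]
            if aa != seq[pos - 1]:
                raise ValueError(
                    f"{path}: chain {chain_id!r} position {pos}: annotation aa "
                    f"{aa!r} does not match sequence {seq[pos - 1]!r}"
                )
            if ss not in SS_STATES:
                raise ValueError(
                    f"{path}: chain {chain_id!r} position {pos}: invalid ss {ss!r}"
                )
            try:
                rsa = float(row["rsa"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: chain {chain_id!r} position {pos}: "
                    f"non-numeric rsa {row['rsa']!r}"
                ) from None
            if not math.isfinite(rsa):
                raise ValueError(
                    f"{path}: chain {chain_id!r} position {pos}: non-finite rsa"
                )
            label = int(row["label"])
            residues.append(Residue(aa=aa, ss=ss, rsa=rsa, label=label))
        chain = AnnotatedChain(chain_id=chain_id, residues=residues)
        if chain.n_rsa_over_ceiling:
            logger.warning(
                "chain %r: %d RSA value(s) above 0.85 (will be clamped at encoding)",
                chain_id, chain.n_rsa_over_ceiling,
            )
        out.append(chain)
    return out


def write_fasta(chains: list[AnnotatedChain], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for chain in chains:
            fh.write(f">{chain.chain_id}\n")
            seq = chain.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_annotations(chains: list[AnnotatedChain], path: str | Path) -> None:
    rows = [
        (c.chain_id, i + 1, r.aa, r.ss, r.rsa, r.label)
        for c in chains
        for i, r in enumerate(c.residues)
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def load_chains(
    fasta_path: str | Path, annotations_path: str | Path
) -> list[AnnotatedChain]:
    """Convenience: FASTA + annotation TSV -> validated chains."""
    return read_annotations(annotations_path, read_fasta(fasta_path))


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level of config must be a mapping")
    return cfg


def load_profile(
    config: str | Path | dict | None, ligand_name: str, **overrides
) -> LigandProfile:
    """Build a :class:`LigandProfile`, layering config and keyword overrides
    on top of the shipped per-ligand defaults.

    The config's ``ligands:`` section is keyed by ligand name; recognised
    per-ligand keys are ``window``, ``rsa_scheme``, ``hydrophobicity_map``,
    ``charge_map`` and ``sa_edges``.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    profile = LigandProfile.default(ligand_name)
    section = (cfg.get("ligands") or {}).get(ligand_name, {})
    mapped = {}
    key_map = {
        "window": "window_length",
        "window_length": "window_length",
        "rsa_scheme": "rsa_scheme",
        "hydrophobicity_map": "hydrophobicity_map",
        "charge_map": "charge_map",
        "sa_edges": "sa_edges",
    }
    for key, value in section.items():
        if key not in key_map:
            raise ValueError(f"unknown profile key {key!r} for ligand {ligand_name!r}")
        mapped[key_map[key]] = value
    mapped.update(overrides)
    return profile.with_overrides(**mapped) if mapped else profile
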