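"""Core domain types for metal ion ligand-binding residue prediction.

A protein chain is represented per residue by four annotations: the amino
acid, a three-state secondary structure (H = alpha-helix, E = beta-strand,
C = coil), a relative solvent accessibility (RSA) value, and a binary flag
marking whether the residue binds the metal ion ligand under study.

Per-ligand defaults (optimal window length and RSA discretization scheme)
are shipped for the ten metal ions the method targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: 20 standard amino acids plus 'X', the vacancy/unknown symbol.
AA_ALPHABET = AA20 + "X"
SS_STATES = "HEC"
RSA_SCHEMES = ("SA_2", "SA_4", "SA_V", "SA_P")

#: RSA values above this are clamped before discretization (the upper end of
#: every discretization scheme's support).
RSA_CEILING = 0.85

#: Per-ligand default sliding-window lengths.
DEFAULT_WINDOW = {
    "Zn2+": 7,
    "Cu2+": 13,
    "Fe2+": 9,
    "Fe3+": 9,
    "Co2+": 11,
    "Ca2+": 9,
    "Mg2+": 9,
    "Mn2+": 7,
    "Na+": 9,
    "K+": 11,
}

#: Per-ligand default RSA discretization scheme.
DEFAULT_RSA_SCHEME = {
    "Zn2+": "SA_4",
    "Cu2+": "SA_4",
    "Fe2+": "SA_4",
    "Fe3+": "SA_V",
    "Co2+": "SA_V",
    "Ca2+": "SA_2",
    "Mg2+": "SA_4",
    "Mn2+": "SA_P",
    "Na+": "SA_V",
    "K+": "SA_V",
}

LIGANDS = tuple(DEFAULT_WINDOW)

#: Six hydrophilicity/hydrophobicity categories ('1'..'6').
DEFAULT_HYDROPHOBICITY = {
    "A": "1", "G": "1",
    "V": "2", "L": "2", "I": "2", "P": "2",
    "F": "3", "W": "3", "Y": "3",
    "S": "4", "T": "4", "C": "4", "M": "4",
    "N": "5", "Q": "5", "D": "5", "E": "5",
    "K": "6", "R": "6", "H": "6",
}

#: Three charge categories: P(ositive), N(egative), U(ncharged).
DEFAULT_CHARGE = {
    aa: ("P" if aa in "KRH" else "N" if aa in "DE" else "U") for aa in AA20
}


@dataclass(frozen=True)
class Residue:
    """One residue's annotations. PAD entries (window padding) carry aa='X'
    and ``None`` for ss/rsa."""

    aa: str
    ss: str | None
    rsa: float | None
    label: int = 0

    @property
    def is_pad(self) -> bool:
        return self.ss is None


PAD_RESIDUE = Residue("X", None, None, 0)


@dataclass
class AnnotatedChain:
    """A protein chain with per-residue annotations.

    Validated on construction: non-empty, amino acids from the 21-letter
    alphabet, secondary structure in {H, E, C}, RSA finite in [0, 1], labels
    binary.  RSA values above 0.85 are legal here (they are clamped later,
    at channel-encoding time); ``n_rsa_over_ceiling`` counts them.
    """

    chain_id: str
    residues: list[Residue]
    n_rsa_over_ceiling: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if not self.chain_id:
            raise ValueError("chain_id must be non-empty")
        if not self.residues:
            raise ValueError(f"chain {self.chain_id!r}: residue list is empty")
        over = 0
        for i, r in enumerate(self.residues):
            where = f"chain {self.chain_id!r} position {i + 1}"
            if r.aa not in AA_ALPHABET or len(r.aa) != 1:
                raise ValueError(f"{where}: invalid amino acid {r.aa!r}")
            if r.ss not in SS_STATES:
                raise ValueError(f"{where}: invalid secondary structure {r.ss!r}")
            if r.rsa is None or not math.isfinite(r.rsa) or not 0.0 <= r.rsa <= 1.0:
                raise ValueError(f"{where}: RSA {r.rsa!r} outside [0, 1]")
            if r.label not in (0, 1):
                raise ValueError(f"{where}: label {r.label!r} not binary")
            if r.rsa > RSA_CEILING:
                over += 1
        self.n_rsa_over_ceiling = over

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def labels(self) -> list[int]:
        return [r.label for r in self.residues]


def _check_category_map(name: str, mapping: dict[str, str], max_categories: int) -> None:
    missing = sorted(set(AA20) - set(mapping))
    if missing:
        raise ValueError(f"{name} map does not cover residues {missing}")
    n_cat = len(set(mapping[a] for a in AA20))
    if n_cat > max_categories:
        raise ValueError(
            f"{name} map has {n_cat} categories, at most {max_categories} allowed"
        )


@dataclass
class LigandProfile:
    """Per-ligand modelling choices: window length, RSA scheme, category maps.

    ``sa_edges`` optionally overrides the interior breakpoints of the
    four-region RSA schemes (see :mod:`ionbind.channels`).
    """

    ligand: str
    window_length: int
    rsa_scheme: str
    hydrophobicity_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_HYDROPHOBICITY)
    )
    charge_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CHARGE))
    sa_edges: dict[str, list[float]] | None = None

    def __post_init__(self) -> None:
        L = self.window_length
        if L % 2 == 0:
            raise ValueError(f"window length must be odd, got {L}")
        if not 5 <= L <= 21:
            raise ValueError(f"window length must lie in [5, 21], got {L}")
        if self.rsa_scheme not in RSA_SCHEMES:
            raise ValueError(
                f"unknown RSA scheme {self.rsa_scheme!r}; expected one of {RSA_SCHEMES}"
            )
        _check_category_map("hydrophobicity", self.hydrophobicity_map, 6)
        _check_category_map("charge", self.charge_map, 3)

    @classmethod
    def default(cls, ligand: str) -> "LigandProfile":
        """The shipped defaults for one of the ten supported ligands."""
        if ligand not in DEFAULT_WINDOW:
            raise ValueError(
                f"unknown ligand {ligand!r}; known ligands: {', '.join(LIGANDS)}"
            )
        return cls(
            ligand=ligand,
            window_length=DEFAULT_WINDOW[ligand],
            rsa_scheme=DEFAULT_RSA_SCHEME[ligand],
        )

    def with_overrides(self, **kwargs) -> "LigandProfile":
        return replace(self, **kwargs)
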