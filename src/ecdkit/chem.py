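"""Peptide sequence parsing and average molar masses.

Growth hormone-releasing peptides are short synthetic peptides that mix
D- and L-amino acids and nonstandard residues — alpha-aminoisobutyric
acid (Aib, alpha-methyl-alanine) and 3-(2-naphthyl)-alanine (2Nal) — and
are usually C-terminally amidated.  Sequences are written as
hyphen-separated residue tokens with optional D-/L- stereo prefixes and a
trailing NH2 marking the amide, e.g. ``L-Tyr-D-Trp-L-Ala-L-Trp-D-Phe-NH2``.

Masses are *average* residue masses (IUPAC average atomic weights summed
over the residue formula): the mass of a free peptide is the sum of its
residue masses plus one water (18.02); C-terminal amidation replaces the
terminal OH by NH2 (-0.98).  Stereo flags are carried but do not affect
mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

#: average residue (monomer) masses in g/mol, water and amide corrections
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "Gly": 57.05,
    "Ala": 71.08,
    "Ser": 87.08,
    "Pro": 97.12,
    "Val": 99.13,
    "Thr": 101.10,
    "Cys": 103.14,
    "Leu": 113.16,
    "Ile": 113.16,
    "Asn": 114.10,
    "Asp": 115.09,
    "Gln": 128.13,
    "Lys": 128.17,
    "Glu": 129.12,
    "Met": 131.19,
    "His": 137.14,
    "Phe": 147.18,
    "Arg": 156.19,
    "Tyr": 163.18,
    "Trp": 186.21,
    # nonstandard residues common in GHRPs
    "Aib": 85.11,   # alpha-aminoisobutyric acid (alpha-methyl-Ala)
    "2Nal": 197.23,  # 3-(2-naphthyl)-alanine
}

WATER_MASS = 18.02
AMIDE_CORRECTION = -0.98

_CANONICAL = {code.lower(): code for code in AVERAGE_RESIDUE_MASS}
_CANONICAL.update({"nal": "2Nal", "2nal": "2Nal", "aib": "Aib"})

# multi-hyphen synonyms, rewritten before tokenization; an embedded D/L
# prefix (e.g. "alpha-Methyl-L-Ala") is preserved
_SYNONYMS = [
    (re.compile(r"(?:α|alpha)-methyl-(?:([dl])-)?ala", re.IGNORECASE), "Aib"),
    (re.compile(r"3-\(2-naphthyl\)-(?:([dl])-)?ala", re.IGNORECASE), "2Nal"),
]


@dataclass
class PeptideSequence:
    """An ordered residue list with stereo flags and the C-terminal amide flag."""

    residues: list[str]
    c_terminal_amide: bool = False
    stereo_flags: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("a peptide needs at least one residue")
        unknown = [r for r in self.residues if r not in AVERAGE_RESIDUE_MASS]
        if unknown:
            raise ValueError(f"unknown residue code(s): {', '.join(unknown)}")
        if not self.stereo_flags:
            self.stereo_flags = [None] * len(self.residues)
        if len(self.stereo_flags) != len(self.residues):
            raise ValueError("one stereo flag per residue required")

    def __len__(self) -> int:
        return len(self.residues)


def parse_sequence(text: str) -> PeptideSequence:
    """Parse a hyphen-separated residue string into a :class:`PeptideSequence`.

    Accepts optional ``D-``/``L-`` prefixes, the synonyms
    ``alpha-Methyl-Ala``/``Aib`` and ``3-(2-Naphthyl)-Ala``/``2Nal``, and a
    trailing ``NH2`` (or ``NH₂``) token setting the amide flag.  Unknown
    tokens raise a ``ValueError`` naming the offending token.
    """
    s = text.strip().replace("NH₂", "NH2").replace("‐", "-").replace("–", "-")
    for pattern, repl in _SYNONYMS:
        s = pattern.sub(lambda m, repl=repl: (m.group(1).upper() + "-" if m.group(1) else "") + repl, s)
    tokens = [t for t in s.split("-") if t]
    if not tokens:
        raise ValueError("empty sequence")

    residues: list[str] = []
    stereo: list[str | None] = []
    amide = False
    pending_stereo: str | None = None
    for pos, token in enumerate(tokens):
        upper = token.upper()
        if upper in ("D", "L"):
            if pending_stereo is not None:
                raise ValueError(f"dangling stereo prefix before {token!r}")
            pending_stereo = upper
        elif upper == "NH2":
            if pos != len(tokens) - 1:
                raise ValueError("NH2 must be the final token")
            if pending_stereo is not None:
                raise ValueError("stereo prefix cannot precede NH2")
            amide = True
        else:
            code = _CANONICAL.get(token.lower())
            if code is None:
                raise ValueError(f"unknown residue token {token!r}")
            residues.append(code)
            stereo.append(pending_stereo)
            pending_stereo = None
    if pending_stereo is not None:
        raise ValueError("sequence ends with a dangling stereo prefix")
    return PeptideSequence(residues, amide, stereo)


def average_mass(seq: PeptideSequence | str) -> float:
    """Average molar mass (g/mol) of a peptide.

    Sum of residue masses + 18.02 for the terminal water, with -0.98 for a
    C-terminal amide.  Comparison against reference tables should round to
    0.1 g/mol, the customary reporting precision.
    """
    if isinstance(seq, str):
        seq = parse_sequence(seq)
    mass = sum(AVERAGE_RESIDUE_MASS[r] for r in seq.residues) + WATER_MASS
    if seq.c_terminal_amide:
        mass += AMIDE_CORRECTION
    return mass
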