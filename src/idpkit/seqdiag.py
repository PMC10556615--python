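"""Sequence-level charge diagnostics and diagram-of-states classification.

Disordered sequences can be placed on the Das-Pappu diagram of states by
their fraction of positively charged residues f+ (K, R; optionally H), the
fraction of negatively charged residues f- (D, E), the fraction of charged
residues FCR = f+ + f-, and the net charge per residue NCPR = f+ - f-.
Region 1 sequences are weak polyampholytes (globule/tadpole), region 3
strong polyampholytes (coils/hairpins), regions 4 and 5 polyelectrolytes
(swollen coils), and region 2 sequences are "Janus": context-dependent,
either compact or extended depending on environment and partners.

The classification is composition-only (invariant to shuffling); charge
patterning measures such as kappa are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO

__all__ = [
    "ChargeProfile",
    "DEFAULT_BOUNDARIES",
    "charge_fractions",
    "das_pappu_class",
    "read_fasta_sequence",
    "REGION_DESCRIPTIONS",
]

STANDARD_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
POSITIVE = set("KR")
NEGATIVE = set("DE")

# Diagram-of-states boundaries (fractions); editable configuration because
# minor published variants of the region borders exist.
DEFAULT_BOUNDARIES = {"r1_fcr": 0.25, "r2_fcr": 0.35, "polyelectrolyte": 0.35}

REGION_DESCRIPTIONS = {
    "R1": "weak polyampholyte (globule or tadpole)",
    "R2": "Janus sequence (context-dependent: compact or extended)",
    "R3": "strong polyampholyte (coil, hairpin or chimera)",
    "R4": "negative polyelectrolyte (swollen coil)",
    "R5": "positive polyelectrolyte (swollen coil)",
}


@dataclass(frozen=True)
class ChargeProfile:
    """Charge composition of a sequence."""

    f_plus: float   # fraction of K/R (and H if included)
    f_minus: float  # fraction of D/E
    length: int

    def __post_init__(self):
        if not (0 <= self.f_plus <= 1 and 0 <= self.f_minus <= 1):
            raise ValueError("charge fractions must lie in [0, 1]")
        if self.fcr > 1 + 1e-12:
            raise ValueError("FCR cannot exceed 1")

    @property
    def fcr(self) -> float:
        """Fraction of charged residues."""
        return self.f_plus + self.f_minus

    @property
    def ncpr(self) -> float:
        """Net charge per residue."""
        return self.f_plus - self.f_minus


def charge_fractions(sequence: str, include_histidine: bool = False) -> ChargeProfile:
    """Charge composition of a 1-letter amino-acid sequence.

    Histidine is uncharged by default (its pKa sits below typical
    experimental pH); ``include_histidine=True`` counts it as positive for
    low-pH conditions.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    positive = POSITIVE | ({"H"} if include_histidine else set())
    for i, aa in enumerate(seq):
        if aa not in STANDARD_ALPHABET:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}")
    n = len(seq)
    return ChargeProfile(
        f_plus=sum(aa in positive for aa in seq) / n,
        f_minus=sum(aa in NEGATIVE for aa in seq) / n,
        length=n,
    )


def das_pappu_class(profile: ChargeProfile, boundaries: dict | None = None) -> str:
    """Diagram-of-states region label for a charge profile.

    FCR < 0.25 -> R1; 0.25 <= FCR <= 0.35 -> R2 (Janus); FCR > 0.35 with
    both f+ and f- at or below 0.35 -> R3; f- > 0.35 >= f+ -> R4;
    f+ > 0.35 >= f- -> R5.  Sequences with both fractions above the
    polyelectrolyte border are strong polyampholytes (R3).
    """
    b = dict(DEFAULT_BOUNDARIES)
    if boundaries:
        b.update(boundaries)
    if profile.fcr < b["r1_fcr"]:
        return "R1"
    if profile.fcr <= b["r2_fcr"]:
        return "R2"
    pe = b["polyelectrolyte"]
    plus_high = profile.f_plus > pe
    minus_high = profile.f_minus > pe
    if minus_high and not plus_high:
        return "R4"
    if plus_high and not minus_high:
        return "R5"
    return "R3"


def read_fasta_sequence(path, record_id: str | None = None) -> str:
    """First (or named) sequence of a FASTA file as a 1-letter string."""
    for record in SeqIO.parse(str(path), "fasta"):
        if record_id is None or record.id == record_id:
            return str(record.seq)
    raise ValueError(f"no matching sequence in {path}")
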