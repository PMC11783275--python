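"""Protein sequences and point-variant specifications.

Variants are written in the common ``XnY`` mutation notation (wild-type
residue, 1-based position on the full-length sequence, variant residue),
with multi-point variations given as comma-joined tokens, e.g.
``"A123G,C150Y"``. Substitutions never shift coordinates, so a multi-point
spec is applied in a single pass with all positions referring to the
wild-type sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Residues accepted in a sequence; X (unknown) is allowed in sequences but
#: is rejected as either side of a substitution.
SEQUENCE_ALPHABET = frozenset(AMINO_ACIDS + "X")

_TOKEN_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class VariantError(ValueError):
    """Malformed, inapplicable, or degenerate variant specification."""


@dataclass(frozen=True)
class ProteinSequence:
    """A named full-length protein sequence."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Substitution:
    """One amino-acid substitution at a 1-based position."""

    wt_aa: str
    pos: int
    var_aa: str

    def __post_init__(self) -> None:
        for aa, label in ((self.wt_aa, "wild-type"), (self.var_aa, "variant")):
            if aa not in SEQUENCE_ALPHABET or aa == "X":
                raise VariantError(f"invalid {label} residue {aa!r}")
        if self.pos < 1:
            raise VariantError(f"position must be >= 1, got {self.pos}")
        if self.wt_aa == self.var_aa:
            raise VariantError(
                f"null substitution {self.wt_aa}{self.pos}{self.var_aa}"
            )

    def inverted(self) -> "Substitution":
        return Substitution(self.var_aa, self.pos, self.wt_aa)

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.pos}{self.var_aa}"


@dataclass(frozen=True)
class VariantSpec:
    """An ordered set of substitutions defining a single- or multi-point variant.

    Positions are strictly increasing and unique; construction normalizes
    the order.
    """

    substitutions: tuple[Substitution, ...]

    def __post_init__(self) -> None:
        if not self.substitutions:
            raise VariantError("empty variant specification")
        ordered = tuple(sorted(self.substitutions, key=lambda s: s.pos))
        positions = [s.pos for s in ordered]
        if len(set(positions)) != len(positions):
            dup = sorted({p for p in positions if positions.count(p) > 1})
            raise VariantError(f"duplicate position(s) {dup}")
        object.__setattr__(self, "substitutions", ordered)

    def __len__(self) -> int:
        return len(self.substitutions)

    def __iter__(self) -> Iterator[Substitution]:
        return iter(self.substitutions)

    def inverted(self) -> "VariantSpec":
        """Spec with wild-type and variant residues swapped per substitution."""
        return VariantSpec(tuple(s.inverted() for s in self.substitutions))

    def __str__(self) -> str:
        return render_variant(self)


def parse_variant(text: str) -> VariantSpec:
    """Parse ``"A23G"`` or ``"A23G,C57Y"`` into a validated :class:`VariantSpec`.

    Order is normalized to increasing position. Raises :class:`VariantError`
    on malformed tokens, null substitutions (``A23A``), duplicate positions,
    or non-positive positions.
    """
    subs = []
    for token in str(text).split(","):
        token = token.strip()
        match = _TOKEN_RE.match(token)
        if match is None:
            raise VariantError(f"malformed variant token {token!r}")
        wt, pos, var = match.groups()
        subs.append(Substitution(wt.upper(), int(pos), var.upper()))
    return VariantSpec(tuple(subs))


def render_variant(spec: VariantSpec) -> str:
    """Canonical string form; ``parse_variant(render_variant(s)) == s``."""
    return ",".join(str(s) for s in spec.substitutions)


def apply_variants(seq: ProteinSequence, spec: VariantSpec) -> ProteinSequence:
    """Apply substitutions to ``seq``, checking wild-type residues.

    The returned sequence has the same length and id and differs from the
    input exactly at the specified positions. A wild-type mismatch signals
    the wrong sequence or wrong coordinates and raises :class:`VariantError`.
    """
    residues = list(seq.residues)
    for sub in spec:
        if sub.pos > len(residues):
            raise VariantError(
                f"position {sub.pos} out of range for {seq.id!r} (L={len(residues)})"
            )
        found = residues[sub.pos - 1]
        if found != sub.wt_aa:
            raise VariantError(
                f"wild-type mismatch at position {sub.pos} of {seq.id!r}: "
                f"expected {sub.wt_aa}, sequence has {found}"
            )
        residues[sub.pos - 1] = sub.var_aa
    return ProteinSequence(seq.id, "".join(residues))


def reverse_variant(
    seq: ProteinSequence, spec: VariantSpec
) -> tuple[ProteinSequence, VariantSpec]:
    """Return the variant sequence together with the inverse specification.

    Thermodynamic reversibility, ddG(A->B) = -ddG(B->A), makes the returned
    pair the natural "reverse variation": applying the returned spec to the
    returned sequence restores ``seq`` exactly (involution).
    """
    return apply_variants(seq, spec), spec.inverted()


def read_fasta(path: str | Path) -> dict[str, ProteinSequence]:
    """Read sequences from a FASTA file, keyed by the first header token."""
    records: dict[str, ProteinSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = ProteinSequence(rec.id, str(rec.seq).upper())
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), 60):
                fh.write(seq.residues[i : i + 60] + "\n")


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a variant TSV with columns ``protein_id``, ``variant``, optional ``ddg``.

    ddG is in kcal/mol; negative values indicate destabilizing variations.
    Variant strings are validated by parsing.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "variant": str})
    required = {"protein_id", "variant"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table {path} lacks column(s) {sorted(missing)}")
    df["variant"].map(parse_variant)  # validation pass
    if "ddg" in df.columns:
        df["ddg"] = df["ddg"].astype(float)
    return df
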