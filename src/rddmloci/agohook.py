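"""AGO-hook domain calling in protein sequences.

AGO-hook domains are intrinsically disordered regions carrying repeated
tryptophans in GW/WG-like sequence contexts that bind ARGONAUTE proteins.
Every W residue is scored over a +/-5 residue window with a position-specific
residue-score matrix; a protein is called AGO-hook-positive when it carries
at least 3 motifs with score >= 6 (both thresholds boundary-inclusive).

The scoring matrix is a configurable artifact (TSV, rows = window offsets,
columns = residues).  The shipped default is a heuristic that rewards glycine
adjacent to the tryptophan (the GW/WG context) plus weakly the polar/acidic
flanking residues common in these domains; it is an approximation, not a
reproduction of any proprietary matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ProteinRecord",
    "MotifHit",
    "AgoHookCall",
    "ScoringMatrix",
    "scan_w_motifs",
    "call_agohook",
    "batch_scan",
    "read_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "-"  # neutral boundary padding, scores 0


@dataclass(frozen=True)
class ProteinRecord:
    """Identifier plus uppercase single-letter sequence (20 residues + X)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id}: empty sequence")
        alphabet = set(AMINO_ACIDS + "X")
        for i, ch in enumerate(self.sequence):
            if ch not in alphabet:
                raise ValueError(
                    f"protein {self.id}: invalid residue {ch!r} at position {i}"
                )


@dataclass(frozen=True)
class MotifHit:
    """One scored tryptophan: 0-based position of the W, the window sequence
    (W +/- flank, boundary-padded with '-') and the summed score."""

    position: int
    window: str
    score: float


@dataclass
class AgoHookCall:
    """Domain-level presence decision for one protein."""

    protein_id: str
    n_motifs: int
    positions: tuple[int, ...]
    span: tuple[int, int] | None
    verdict: bool


class ScoringMatrix:
    """Position-specific residue scores over window offsets -flank..+flank."""

    def __init__(self, table: pd.DataFrame, flank: int = 5):
        expected = list(range(-flank, flank + 1))
        if list(table.index) != expected:
            raise ValueError(f"matrix rows must be offsets {expected}")
        self.table = table.astype(float)
        self.flank = flank

    def score(self, offset: int, residue: str) -> float:
        if residue == PAD:
            return 0.0
        if residue in self.table.columns:
            return float(self.table.at[offset, residue])
        return 0.0

    @classmethod
    def default_plant_like(cls, flank: int = 5) -> "ScoringMatrix":
        """Heuristic GW/WG-context matrix: G adjacent to the W scores 3 on
        either side, and S/T/D/E at offsets +/-2..3 score 0.5."""
        table = pd.DataFrame(
            0.0,
            index=range(-flank, flank + 1),
            columns=list(AMINO_ACIDS + "X"),
        )
        table.at[-1, "G"] = 3.0
        table.at[1, "G"] = 3.0
        for off in (-3, -2, 2, 3):
            for res in "STDE":
                table.at[off, res] = 0.5
        return cls(table, flank)

    @classmethod
    def from_tsv(cls, path) -> "ScoringMatrix":
        table = pd.read_csv(path, sep="\t", index_col=0)
        table.index = table.index.astype(int)
        table.index.name = None
        flank = int(table.index.max())
        return cls(table, flank)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="offset")


def scan_w_motifs(
    p: ProteinRecord,
    matrix: ScoringMatrix | None = None,
    flank: int = 5,
) -> list[MotifHit]:
    """Score every tryptophan of a protein over its +/-flank window.

    Sequence boundaries are padded with a neutral zero-scoring symbol.  Hits
    come back in sequence order.
    """
    if matrix is None:
        matrix = ScoringMatrix.default_plant_like(flank)
    seq = p.sequence
    hits = []
    for i, ch in enumerate(seq):
        if ch != "W":
            continue
        window = []
        score = 0.0
        for off in range(-matrix.flank, matrix.flank + 1):
            j = i + off
            res = seq[j] if 0 <= j < len(seq) else PAD
            window.append(res)
            if off != 0:
                score += matrix.score(off, res)
            else:
                score += matrix.score(0, "W")
        hits.append(MotifHit(i, "".join(window), score))
    return hits


def call_agohook(
    hits: list[MotifHit],
    min_score: float = 6.0,
    min_motifs: int = 3,
    protein_id: str = "",
) -> AgoHookCall:
    """Domain call: verdict is True iff >= min_motifs hits score >= min_score
    (both inclusive); the span runs from the first to the last qualifying W."""
    qualifying = [h for h in hits if h.score >= min_score]
    positions = tuple(h.position for h in qualifying)
    span = (positions[0], positions[-1]) if positions else None
    return AgoHookCall(
        protein_id=protein_id,
        n_motifs=len(qualifying),
        positions=positions,
        span=span,
        verdict=len(qualifying) >= min_motifs,
    )


def batch_scan(
    proteins: list[ProteinRecord],
    matrix: ScoringMatrix | None = None,
    min_score: float = 6.0,
    min_motifs: int = 3,
) -> pd.DataFrame:
    """Scan a proteome; one row per protein in input order.

    Duplicate identifiers are an error (they would make rows ambiguous).
    """
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate protein identifier {dup!r}")
    rows = []
    for p in proteins:
        call = call_agohook(scan_w_motifs(p, matrix), min_score, min_motifs, p.id)
        rows.append(
            {
                "id": p.id,
                "n_motifs": call.n_motifs,
                "positions": ",".join(map(str, call.positions)),
                "span": f"{call.span[0]}-{call.span[1]}" if call.span else "",
                "verdict": call.verdict,
            }
        )
    return pd.DataFrame(rows, columns=["id", "n_motifs", "positions", "span", "verdict"])


def read_fasta(path) -> list[ProteinRecord]:
    from Bio import SeqIO

    return [
        ProteinRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
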