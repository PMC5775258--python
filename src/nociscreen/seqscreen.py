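"""Proline-directed kinase (Cdk5) substrate scanning over protein sequences.

Cdk5 is a Ser/Thr kinase whose preferred substrates carry the consensus
(S/T)PX(K/H/R): a phospho-acceptor serine or threonine, an obligate proline
at +1, any residue at +2 and a basic/histidine residue at +3.  In ankyrin
repeats the same acceptor frequently sits in a T/SxxH tetrapeptide (His at
+3), so the two patterns overlap whenever the consensus +3 residue is His.

This module scans protein sequences for both patterns, optionally scores
candidate sites with a user-supplied position-specific scoring matrix
(PSSM), removes sites that fall in annotated transmembrane or extracellular
segments (a kinase in the cytosol cannot reach them), and extracts the
10-residue substrate window (acceptor-3 .. acceptor+6, obligate proline at
window position 5) used for peptide kinase assays.

All residue coordinates are 1-based and inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "TOPOLOGY_KINDS",
    "TopologySegment",
    "ProteinRecord",
    "MotifSite",
    "ScoringMatrix",
    "PeptideWindow",
    "read_fasta",
    "read_topology",
    "attach_topology",
    "read_pssm",
    "read_gene_set",
    "scan_consensus",
    "scan_txxh",
    "merge_sites",
    "score_site",
    "filter_topology",
    "extract_peptide",
    "screen_proteome",
    "write_candidates",
]

#: The 20 canonical amino acids, one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS) | {"X"}

TOPOLOGY_KINDS = ("cytoplasmic", "transmembrane", "extracellular", "unknown")

# Required positions are matched against explicit residue sets, so an 'X'
# (unknown residue) can never satisfy them; the wildcard at +2 accepts
# anything, X included.
_CONSENSUS_RE = re.compile(r"(?=([ST])P[A-Z][KHR])")
_TXXH_RE = re.compile(r"(?=([ST])[A-Z][A-Z]H)")


class FormatError(ValueError):
    """Raised for malformed input files (FASTA, topology, PSSM)."""


@dataclass(frozen=True)
class TopologySegment:
    """A labelled membrane-topology interval, 1-based inclusive."""

    kind: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in TOPOLOGY_KINDS:
            raise ValueError(f"unknown topology kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad segment bounds [{self.start}, {self.end}]")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class ProteinRecord:
    """A protein sequence plus optional membrane-topology annotation."""

    id: str
    sequence: str
    topology: list[TopologySegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise FormatError(f"{self.id}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise FormatError(
                f"{self.id}: invalid residue(s) {''.join(sorted(bad))!r}"
            )
        n = len(self.sequence)
        segs = sorted(self.topology, key=lambda s: s.start)
        for seg in segs:
            if seg.end > n:
                raise ValueError(
                    f"{self.id}: segment [{seg.start},{seg.end}] exceeds length {n}"
                )
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(f"{self.id}: overlapping topology segments")
        self.topology = segs

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        return self.sequence[pos - 1]

    def topology_at(self, pos: int) -> str:
        """Topology label at a 1-based position; 'unknown' if unannotated."""
        for seg in self.topology:
            if pos in seg:
                return seg.kind
        return "unknown"


@dataclass
class MotifSite:
    """A candidate phospho-acceptor position within one protein."""

    protein_id: str
    acceptor_pos: int  # 1-based index of the S/T
    acceptor_res: str
    motif_class: str  # consensus | txxh | both
    window: str  # the matched 4-mer
    pssm_score: float | None = None
    topology_kind: str = "unknown"


@dataclass
class ScoringMatrix:
    """Log-odds weights per (offset, residue); offsets relative to acceptor.

    ``values[offset][residue]`` must exist for every canonical residue at
    every covered offset.  'X' always scores 0.
    """

    values: Mapping[int, Mapping[str, float]]

    def __post_init__(self) -> None:
        for off, row in self.values.items():
            missing = set(AMINO_ACIDS) - set(row)
            if missing:
                raise FormatError(
                    f"PSSM offset {off:+d} missing residues {''.join(sorted(missing))}"
                )

    @property
    def offsets(self) -> list[int]:
        return sorted(self.values)

    @classmethod
    def uniform_zero(cls, offsets: Iterable[int] = range(-4, 6)) -> "ScoringMatrix":
        """All-zero matrix over the default acceptor-relative window."""
        return cls({off: {aa: 0.0 for aa in AMINO_ACIDS} for off in offsets})


@dataclass
class PeptideWindow:
    """A 10-residue substrate window: acceptor at position 4, proline at 5."""

    protein_id: str
    acceptor_pos: int
    sequence10: str
    truncated: bool = False


# ---------------------------------------------------------------------------
# input readers


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased and a single terminal ``*`` (stop) is stripped.
    Duplicate ids, empty files and non-amino-acid characters raise
    :class:`FormatError`.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FormatError(f"duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        seq = str(entry.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def read_topology(path: str | Path) -> dict[str, list[TopologySegment]]:
    """Read a topology TSV (protein_id, kind, start, end) into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "kind": str})
    required = {"protein_id", "kind", "start", "end"}
    if not required <= set(df.columns):
        raise FormatError(f"topology file needs columns {sorted(required)}")
    out: dict[str, list[TopologySegment]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.protein_id, []).append(
            TopologySegment(kind=row.kind, start=int(row.start), end=int(row.end))
        )
    return out


def attach_topology(
    records: Sequence[ProteinRecord], topology: Mapping[str, list[TopologySegment]]
) -> list[ProteinRecord]:
    """Return copies of ``records`` carrying their topology annotations."""
    return [
        ProteinRecord(r.id, r.sequence, list(topology.get(r.id, [])))
        for r in records
    ]


def read_pssm(path: str | Path) -> ScoringMatrix:
    """Read a PSSM TSV: first column ``offset``, one column per residue."""
    df = pd.read_csv(path, sep="\t")
    if "offset" not in df.columns:
        raise FormatError("PSSM file needs an 'offset' column")
    df = df.set_index("offset")
    values = {
        int(off): {str(aa): float(df.at[off, aa]) for aa in df.columns}
        for off in df.index
    }
    return ScoringMatrix(values)


def read_gene_set(path: str | Path) -> set[str]:
    """Read a one-id-per-line gene-set file; blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


# ---------------------------------------------------------------------------
# scanning


def _scan(record: ProteinRecord, pattern: re.Pattern[str], motif_class: str) -> list[MotifSite]:
    sites = []
    for m in pattern.finditer(record.sequence):
        pos = m.start() + 1
        sites.append(
            MotifSite(
                protein_id=record.id,
                acceptor_pos=pos,
                acceptor_res=m.group(1),
                motif_class=motif_class,
                window=record.sequence[m.start() : m.start() + 4],
                topology_kind=record.topology_at(pos),
            )
        )
    return sites


def scan_consensus(record: ProteinRecord) -> list[MotifSite]:
    """All (S/T)PX(K/H/R) acceptor sites, overlaps included, by position."""
    return _scan(record, _CONSENSUS_RE, "consensus")


def scan_txxh(record: ProteinRecord) -> list[MotifSite]:
    """All T/SxxH acceptor sites (ankyrin-repeat tetrapeptide), by position."""
    return _scan(record, _TXXH_RE, "txxh")


def merge_sites(
    consensus: Sequence[MotifSite], txxh: Sequence[MotifSite]
) -> list[MotifSite]:
    """Merge the two scans; shared acceptors get ``motif_class='both'``.

    A site appears once per acceptor position; ordering is by position.
    """
    by_pos: dict[int, MotifSite] = {}
    for s in consensus:
        by_pos[s.acceptor_pos] = replace(s)
    for s in txxh:
        if s.acceptor_pos in by_pos:
            by_pos[s.acceptor_pos].motif_class = "both"
        else:
            by_pos[s.acceptor_pos] = replace(s)
    return [by_pos[p] for p in sorted(by_pos)]


def score_site(site: MotifSite, record: ProteinRecord, matrix: ScoringMatrix) -> float:
    """PSSM log-odds score: sum of weights over the matrix's offsets.

    Offsets that fall outside the sequence contribute 0, as does an 'X'
    residue at any position.
    """
    total = 0.0
    for off in matrix.offsets:
        pos = site.acceptor_pos + off
        if not (1 <= pos <= len(record)):
            continue
        aa = record.residue(pos)
        if aa == "X":
            continue
        total += matrix.values[off][aa]
    return total


def filter_topology(
    sites: Sequence[MotifSite], record: ProteinRecord
) -> list[MotifSite]:
    """Drop sites in transmembrane/extracellular segments.

    Sites in cytoplasmic segments are kept; sites at unannotated positions
    are kept and labelled 'unknown' — only demonstrably inaccessible sites
    are excluded.  Idempotent.
    """
    kept = []
    for s in sites:
        kind = record.topology_at(s.acceptor_pos)
        if kind in ("transmembrane", "extracellular"):
            continue
        kept.append(replace(s, topology_kind=kind))
    return kept


def extract_peptide(record: ProteinRecord, site: MotifSite) -> PeptideWindow:
    """The 10-mer assay window acceptor-3 .. acceptor+6.

    The acceptor lands at window position 4 and the obligate proline at
    position 5.  Windows clipped by a sequence end are flagged truncated.
    """
    start = site.acceptor_pos - 3
    end = site.acceptor_pos + 6
    lo = max(start, 1)
    hi = min(end, len(record))
    return PeptideWindow(
        protein_id=record.id,
        acceptor_pos=site.acceptor_pos,
        sequence10=record.sequence[lo - 1 : hi],
        truncated=(lo != start or hi != end),
    )


_CANDIDATE_COLUMNS = [
    "protein_id",
    "acceptor_pos",
    "acceptor_res",
    "motif_class",
    "window",
    "peptide10",
    "topology_kind",
    "pssm_score",
]


def screen_proteome(
    records: Sequence[ProteinRecord],
    matrix: ScoringMatrix | None = None,
    expressed_gene_set: set[str] | None = None,
) -> pd.DataFrame:
    """Full substrate screen: scan, topology-filter, restrict, score.

    Runs the consensus scan on every record (tagging sites that also match
    T/SxxH as 'both'), removes transmembrane/extracellular sites, optionally
    restricts to proteins whose id is in ``expressed_gene_set``, and scores
    surviving sites when a PSSM is given.  One row per site, ordered by
    (protein_id, acceptor_pos).
    """
    rows = []
    for rec in sorted(records, key=lambda r: r.id):
        if expressed_gene_set is not None and rec.id not in expressed_gene_set:
            continue
        consensus = scan_consensus(rec)
        txxh_positions = {s.acceptor_pos for s in scan_txxh(rec)}
        for s in consensus:
            if s.acceptor_pos in txxh_positions:
                s.motif_class = "both"
        for s in filter_topology(consensus, rec):
            pep = extract_peptide(rec, s)
            score = score_site(s, rec, matrix) if matrix is not None else None
            rows.append(
                (
                    s.protein_id,
                    s.acceptor_pos,
                    s.acceptor_res,
                    s.motif_class,
                    s.window,
                    pep.sequence10,
                    s.topology_kind,
                    score,
                )
            )
    return pd.DataFrame(rows, columns=_CANDIDATE_COLUMNS)


def write_candidates(table: pd.DataFrame, path: str | Path) -> None:
    """Write the candidate table as TSV."""
    table.to_csv(path, sep="\t", index=False)
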