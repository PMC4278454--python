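"""Sequence I/O and codon-aware alignment.

The central container is :class:`CodonAlignment`: an in-frame, gap-aware
alignment of coding sequences, optionally annotated with an exon map and a
mask of low-quality column ranges.  Alignments are built by aligning the
translated proteins and back-threading the codons, so gaps always fall on
codon boundaries in multiples of three.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import codon as _codon


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class CodonAlignment:
    """In-frame codon alignment with optional exon map and column mask.

    ``records`` maps label -> aligned CDS (upper-case, '-' gaps).
    ``exon_map`` is a list of (exon_id, start, end) half-open ranges in
    alignment-column coordinates.  ``mask`` is a tuple of half-open column
    ranges removed from downstream analyses; masking never splits a codon.
    """

    records: tuple[tuple[str, str], ...]
    exon_map: tuple[tuple[int, int, int], ...] | None = None
    mask: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if not self.records:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise AlignmentError("records differ in aligned length")
        (length,) = lengths
        if length % 3:
            raise AlignmentError("alignment length is not a multiple of 3")
        for label, seq in self.records:
            for cstart in range(0, length, 3):
                cod = seq[cstart : cstart + 3]
                n_gap = cod.count("-")
                if n_gap not in (0, 3):
                    raise AlignmentError(
                        f"gap does not respect codon boundaries in {label!r} at column {cstart}"
                    )
        for start, end in self.mask:
            if start % 3 or end % 3 or not 0 <= start < end <= length:
                raise AlignmentError(f"mask range ({start}, {end}) does not align to codons")
        masked = self.masked_columns()
        for label, seq in self.records:
            for ci, cstart in enumerate(range(0, length, 3)):
                cod = seq[cstart : cstart + 3]
                if cod in _codon.STOP_CODONS and cstart not in masked:
                    raise AlignmentError(f"internal stop codon in {label!r} at codon {ci}")

    # -- construction ---------------------------------------------------
    @classmethod
    def from_dict(cls, records: dict[str, str], **kw) -> "CodonAlignment":
        return cls(tuple((k, v.upper()) for k, v in records.items()), **kw)

    # -- basic properties -----------------------------------------------
    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.records)

    def __getitem__(self, label: str) -> str:
        for lab, seq in self.records:
            if lab == label:
                return seq
        raise KeyError(label)

    def masked_columns(self) -> set[int]:
        cols: set[int] = set()
        for start, end in self.mask:
            cols.update(range(start, end))
        return cols

    def unmasked_codon_starts(self) -> list[int]:
        masked = self.masked_columns()
        return [c for c in range(0, self.length, 3) if c not in masked]

    # -- views ----------------------------------------------------------
    def codon_matrix(self, labels: list[str] | None = None) -> np.ndarray:
        """(n_seq, n_codon) matrix of codon indices over unmasked columns.

        Gap / ambiguous / stop codons are encoded as -1.
        """
        labels = list(labels) if labels is not None else list(self.labels)
        starts = self.unmasked_codon_starts()
        mat = np.empty((len(labels), len(starts)), dtype=int)
        for i, lab in enumerate(labels):
            seq = self[lab]
            mat[i] = [_codon.CODON_INDEX.get(seq[s : s + 3], -1) for s in starts]
        return mat

    def pairwise_codons(self, a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
        """Complete-case codon indices for a pair (gapped columns dropped)."""
        mat = self.codon_matrix([a, b])
        keep = (mat >= 0).all(axis=0)
        return mat[0, keep], mat[1, keep]

    def drop_column_ranges(self, ranges: list[tuple[int, int]]) -> "CodonAlignment":
        """Physically remove half-open column ranges (codon aligned)."""
        drop: set[int] = set()
        for start, end in ranges:
            if start % 3 or end % 3:
                raise AlignmentError("column range does not align to codons")
            drop.update(range(start, end))
        keep = [c for c in range(self.length) if c not in drop]
        if not keep:
            raise AlignmentError("empty alignment after removing columns")
        new_records = tuple((lab, "".join(seq[c] for c in keep)) for lab, seq in self.records)
        old_to_new = {c: i for i, c in enumerate(keep)}
        new_mask = []
        for start, end in self.mask:
            cols = [old_to_new[c] for c in range(start, end) if c in old_to_new]
            if cols:
                new_mask.append((min(cols), max(cols) + 1))
        new_exons = None
        if self.exon_map is not None:
            new_exons = []
            for eid, start, end in self.exon_map:
                cols = [old_to_new[c] for c in range(start, end) if c in old_to_new]
                if cols:
                    new_exons.append((eid, min(cols), max(cols) + 1))
            new_exons = tuple(new_exons)
        return CodonAlignment(new_records, exon_map=new_exons, mask=tuple(new_mask))


# ---------------------------------------------------------------------------
# FASTA round trip
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    recs = [SeqRecord(Seq(seq), id=label, description="") for label, seq in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def fasta_string(records: dict[str, str]) -> str:
    buf = io.StringIO()
    recs = [SeqRecord(Seq(seq), id=label, description="") for label, seq in records.items()]
    SeqIO.write(recs, buf, "fasta")
    return buf.getvalue()


def read_exon_map(path) -> list[tuple[int, int, int]]:
    df = pd.read_csv(path, sep="\t")
    return [(int(r.exon), int(r.start), int(r.end)) for r in df.itertuples()]


def write_exon_map(exons: list[tuple[int, int, int]], path) -> None:
    pd.DataFrame(exons, columns=["exon", "start", "end"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Protein-guided codon alignment
# ---------------------------------------------------------------------------

def translate_cds(label: str, cds: str) -> str:
    """Translate an in-frame CDS, stripping one trailing stop codon if present."""
    if len(cds) % 3:
        raise AlignmentError(f"{label!r}: CDS length {len(cds)} is not a multiple of 3")
    if cds[-3:].upper() in _codon.STOP_CODONS:
        cds = cds[:-3]
    protein = str(Seq(cds).translate())
    if "*" in protein:
        raise AlignmentError(f"{label!r}: internal stop codon at codon index {protein.index('*')}")
    if not set(cds.upper()) <= set("ACGT"):
        bad = sorted(set(cds.upper()) - set("ACGT"))
        raise AlignmentError(f"{label!r}: unsupported characters {bad} in CDS")
    return protein


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    return aligner


def _align_protein_pair(p1: str, p2: str) -> tuple[str, str]:
    aln = _protein_aligner().align(p1, p2)[0]
    lines = str(aln).splitlines()
    # Biopython's format: target / match / query rows, possibly wrapped
    a_parts, b_parts = [], []
    for i in range(0, len(lines), 4):
        a_parts.append(lines[i].split()[-1] if lines[i].split() else "")
        if i + 2 < len(lines):
            b_parts.append(lines[i + 2].split()[-1] if lines[i + 2].split() else "")
    a, b = "".join(a_parts), "".join(b_parts)
    # Fall back to coordinate reconstruction (robust to formatting changes)
    if a.replace("-", "") != p1 or b.replace("-", "") != p2:
        a, b = _aligned_from_coords(aln, p1, p2)
    return a, b


def _aligned_from_coords(aln, p1: str, p2: str) -> tuple[str, str]:
    a_out, b_out = [], []
    pa = pb = 0
    for (a_s, a_e), (b_s, b_e) in zip(*aln.aligned):
        while pa < a_s:
            a_out.append(p1[pa]); b_out.append("-"); pa += 1
        while pb < b_s:
            a_out.append("-"); b_out.append(p2[pb]); pb += 1
        a_out.append(p1[a_s:a_e]); b_out.append(p2[b_s:b_e])
        pa, pb = a_e, b_e
    while pa < len(p1):
        a_out.append(p1[pa]); b_out.append("-"); pa += 1
    while pb < len(p2):
        a_out.append("-"); b_out.append(p2[pb]); pb += 1
    return "".join(a_out), "".join(b_out)


def _merge_into_master(master: list[str], ref_pair: str, new_pair: str) -> tuple[list[str], str]:
    """Merge a (ref, new) pairwise alignment into a master alignment whose
    first row is the (possibly gapped) reference."""
    mi = pj = 0
    out_master = [[] for _ in master]
    out_new = []
    m_len, p_len = len(master[0]), len(ref_pair)
    while mi < m_len or pj < p_len:
        if mi < m_len and master[0][mi] == "-":
            for r, row in enumerate(master):
                out_master[r].append(row[mi])
            out_new.append("-")
            mi += 1
        elif pj < p_len and ref_pair[pj] == "-":
            for r in range(len(master)):
                out_master[r].append("-")
            out_new.append(new_pair[pj])
            pj += 1
        else:
            for r, row in enumerate(master):
                out_master[r].append(row[mi])
            out_new.append(new_pair[pj])
            mi += 1
            pj += 1
    return ["".join(r) for r in out_master], "".join(out_new)


def build_codon_alignment(
    cds_records: dict[str, str],
    exon_map: list[tuple[int, int, int]] | None = None,
    protein_aligner=None,
) -> CodonAlignment:
    """Protein-guided codon alignment.

    Proteins are aligned with Needleman–Wunsch under BLOSUM62 (pairs), or
    progressively against the first record for more than two sequences, and
    the alignment is back-threaded onto codons.  A custom ``protein_aligner``
    may be supplied as ``f(p1, p2) -> (aligned1, aligned2)``.
    """
    if not cds_records:
        raise AlignmentError("no sequences supplied")
    labels = list(cds_records)
    cds = {lab: cds_records[lab].upper() for lab in labels}
    stripped = {
        lab: (s[:-3] if s[-3:] in _codon.STOP_CODONS else s) for lab, s in cds.items()
    }
    proteins = {lab: translate_cds(lab, cds[lab]) for lab in labels}
    align_pair = protein_aligner or _align_protein_pair

    if len(labels) == 1:
        aligned_prot = {labels[0]: proteins[labels[0]]}
    else:
        ref = labels[0]
        a_ref, a_new = align_pair(proteins[ref], proteins[labels[1]])
        master = [a_ref, a_new]
        order = [ref, labels[1]]
        for lab in labels[2:]:
            p_ref, p_new = align_pair(proteins[ref], proteins[lab])
            # re-walk against the master's reference row (row 0)
            master, merged_new = _merge_into_master(master, p_ref, p_new)
            master.append(merged_new)
            order.append(lab)
        aligned_prot = dict(zip(order, master))

    out = {}
    for lab in labels:
        codons = _codon.codons_of(stripped[lab])
        pieces, k = [], 0
        for aa in aligned_prot[lab]:
            if aa == "-":
                pieces.append("---")
            else:
                pieces.append(codons[k])
                k += 1
        out[lab] = "".join(pieces)
    return CodonAlignment.from_dict(out, exon_map=tuple(exon_map) if exon_map else None)


# ---------------------------------------------------------------------------
# Automated masking of poorly aligned regions
# ---------------------------------------------------------------------------

def mask_poor_regions(
    aln: CodonAlignment,
    max_gap_fraction: float = 0.5,
    window_codons: int = 5,
    min_window_identity: float = 0.4,
) -> CodonAlignment:
    """Mask codon columns with >``max_gap_fraction`` gaps and windows of
    ``window_codons`` codons whose mean pairwise nucleotide identity falls
    below ``min_window_identity``.

    The rule is iterated to a fixpoint, so the operation is idempotent.
    """
    n_seq = len(aln.records)
    seqs = [seq for _, seq in aln.records]
    masked = aln.masked_columns()

    def gap_frac(cstart: int) -> float:
        return sum(1 for s in seqs if "-" in s[cstart : cstart + 3]) / n_seq

    def window_identity(starts: list[int]) -> float:
        idents, total = 0, 0
        for i in range(n_seq):
            for j in range(i + 1, n_seq):
                for cs in starts:
                    for k in range(3):
                        a, b = seqs[i][cs + k], seqs[j][cs + k]
                        if a != "-" and b != "-":
                            total += 1
                            idents += a == b
        return idents / total if total else 1.0

    changed = True
    while changed:
        changed = False
        starts = [c for c in range(0, aln.length, 3) if c not in masked]
        for cs in starts:
            if gap_frac(cs) > max_gap_fraction:
                masked.update(range(cs, cs + 3))
                changed = True
        starts = [c for c in range(0, aln.length, 3) if c not in masked]
        win_n = min(window_codons, len(starts)) or 1
        for w in range(len(starts) - win_n + 1):
            win = starts[w : w + win_n]
            if window_identity(win) < min_window_identity:
                for cs in win:
                    masked.update(range(cs, cs + 3))
                changed = True

    if len(masked) >= aln.length:
        raise AlignmentError("empty alignment after masking")
    # compress into ranges
    ranges, cur = [], None
    for c in range(0, aln.length, 3):
        if c in masked:
            if cur is None:
                cur = [c, c + 3]
            else:
                cur[1] = c + 3
        elif cur is not None:
            ranges.append(tuple(cur))
            cur = None
    if cur is not None:
        ranges.append(tuple(cur))
    return replace(aln, mask=tuple(ranges))
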