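"""Genome input: contig loading, filtering, and six-frame ORF enumeration.

Contigs are read from FASTA or GenBank flat files (format auto-detected by
content). Contigs under ``min_length`` nucleotides are discarded, and when a
file contains more than ``max_contigs`` contigs only the largest are kept.
Open reading frames are called by simple stop-to-stop scanning on all six
frames with bacterial start codons (ATG/GTG/TTG); no coding-potential model
is applied.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

from bgcforge.errors import FormatError, InputError

DEFAULT_MIN_CONTIG_LENGTH = 500
DEFAULT_MAX_CONTIGS = 1000
DEFAULT_MIN_ORF_AA = 60
DEFAULT_MAX_FILE_BYTES = 50 * 1024 * 1024

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
_TRANSLATION_TABLE = 11  # standard bacterial code


@dataclass(frozen=True)
class Contig:
    """A nucleotide record (A/C/G/T/N, uppercase)."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Orf:
    """A translated candidate coding region.

    Coordinates are 1-based inclusive on the forward strand (GenBank
    convention) and span start codon through stop codon. ``frame`` is 1-3 for
    the forward strand, 4-6 for the reverse.
    """

    id: str
    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    frame: int
    protein: str
    domains: list = field(default_factory=list, compare=False)

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1

    @property
    def frame_key(self) -> tuple[str, int]:
        """Strand and codon phase on the contig; ORFs sharing this key are
        considered to lie 'in the same frame'."""
        if self.strand == "+":
            return ("+", self.start % 3)
        return ("-", self.end % 3)


def _sniff_format(path: str) -> str:
    with open(path, "r", errors="replace") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                return "fasta"
            if stripped.upper().startswith("LOCUS"):
                return "genbank"
            raise FormatError(f"{path}: unrecognized sequence format")
    raise InputError(f"{path}: empty file")


def load_contigs(
    path: str,
    max_contigs: int = DEFAULT_MAX_CONTIGS,
    min_length: int = DEFAULT_MIN_CONTIG_LENGTH,
    max_bytes: int = DEFAULT_MAX_FILE_BYTES,
) -> list[Contig]:
    """Read contigs, drop short ones, and cap the contig count.

    Contigs shorter than ``min_length`` nucleotides are discarded. If more
    than ``max_contigs`` remain, only the ``max_contigs`` largest (ties broken
    by input order) are returned, in input order.
    """
    if not os.path.exists(path):
        raise InputError(f"{path}: no such file")
    if os.path.getsize(path) == 0:
        raise InputError(f"{path}: empty file")
    if os.path.getsize(path) > max_bytes:
        raise InputError(f"{path}: exceeds input size limit ({max_bytes} bytes)")
    fmt = _sniff_format(path)
    try:
        records = list(SeqIO.parse(path, fmt))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise FormatError(f"{path}: failed to parse as {fmt}: {exc}") from exc
    if not records:
        raise InputError(f"{path}: no sequence records")
    contigs = [
        Contig(id=rec.id, sequence=str(rec.seq).upper())
        for rec in records
    ]
    contigs = [c for c in contigs if c.length >= min_length]
    if len(contigs) > max_contigs:
        # keep the max_contigs largest; stable on input order for ties
        order = sorted(
            range(len(contigs)), key=lambda i: (-contigs[i].length, i)
        )[:max_contigs]
        keep = set(order)
        contigs = [c for i, c in enumerate(contigs) if i in keep]
    return contigs


def _translate(codons: str) -> str:
    protein = str(Seq(codons).translate(table=_TRANSLATION_TABLE))
    return protein.replace("*", "")


def _scan_frame(seq: str, offset: int, min_aa: int):
    """Yield (start_nt, end_nt, protein) tuples, 0-based half-open on the
    given (forward-oriented) sequence, for one reading frame."""
    n = len(seq)
    segment_start = offset
    pos = offset
    while pos + 3 <= n:
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            yield from _emit_orf(seq, segment_start, pos + 3, True, min_aa)
            segment_start = pos + 3
        pos += 3
    # trailing segment without a stop codon
    yield from _emit_orf(seq, segment_start, pos, False, min_aa)


def _emit_orf(seq: str, seg_start: int, seg_end: int, has_stop: bool, min_aa: int):
    """Find the first start codon in [seg_start, seg_end) and emit the ORF."""
    coding_end = seg_end - 3 if has_stop else seg_end
    pos = seg_start
    while pos + 3 <= coding_end:
        if seq[pos : pos + 3] in START_CODONS:
            n_codons = (coding_end - pos) // 3
            if n_codons >= min_aa:
                protein = "M" + _translate(seq[pos + 3 : coding_end])
                yield (pos, seg_end, protein)
            return
        pos += 3


def find_orfs(contig: Contig, min_aa: int = DEFAULT_MIN_ORF_AA) -> list[Orf]:
    """Enumerate start-to-stop ORFs of >= ``min_aa`` residues on all six frames.

    Returned coordinates are on the forward strand, 1-based inclusive,
    including the stop codon when present. Order is by (start, end, strand).
    """
    if not contig.sequence:
        return []
    seq = contig.sequence
    rc = str(Seq(seq).reverse_complement())
    n = len(seq)
    orfs: list[Orf] = []
    for offset in range(3):
        for s, e, protein in _scan_frame(seq, offset, min_aa):
            orfs.append(
                Orf(
                    id="",
                    contig_id=contig.id,
                    start=s + 1,
                    end=e,
                    strand="+",
                    frame=offset + 1,
                    protein=protein,
                )
            )
        for s, e, protein in _scan_frame(rc, offset, min_aa):
            # map reverse-strand coordinates back onto the forward axis
            orfs.append(
                Orf(
                    id="",
                    contig_id=contig.id,
                    start=n - e + 1,
                    end=n - s,
                    strand="-",
                    frame=offset + 4,
                    protein=protein,
                )
            )
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return [
        Orf(
            id=f"{contig.id}_orf{i + 1}",
            contig_id=o.contig_id,
            start=o.start,
            end=o.end,
            strand=o.strand,
            frame=o.frame,
            protein=o.protein,
        )
        for i, o in enumerate(orfs)
    ]
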