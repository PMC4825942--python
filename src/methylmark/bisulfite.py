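"""Amplicon bisulfite-sequencing analysis.

Bisulfite treatment converts unmethylated cytosine to uracil (read as T
after PCR) while 5-methylcytosine is protected.  Sequencing a PCR amplicon
of the converted template therefore reads each CpG cytosine as C
(methylated) or T (unmethylated), and every non-CpG cytosine as T — the
latter providing a per-read conversion-efficiency control, because non-CpG
methylation is essentially absent in mammalian somatic DNA.

This module covers the computational chain for clone/amplicon bisulfite
sequencing of a known promoter region: CpG discovery on the untreated
reference, TSS-relative coordinate conversion, in-silico conversion of the
reference into an alignment template, ungapped alignment of reads against
it, per-read per-site methylation calls, and per-site summaries (the text
twin of a lollipop diagram).

Coordinates are genomic 1-based inclusive throughout; BED export converts
to 0-based half-open.  "Position" of a CpG always refers to its C on the
plus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceSequence",
    "CpGSite",
    "BisulfiteRead",
    "Alignment",
    "MethylationCallMatrix",
    "find_cpg_sites",
    "genomic_to_tss_offset",
    "tss_offset_to_genomic",
    "convert_reference",
    "align_read",
    "call_methylation",
    "site_summary",
    "sites_to_bed",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

METHYLATED, UNMETHYLATED, MISSING = 1, 0, -1
CALL_SYMBOLS = {METHYLATED: "M", UNMETHYLATED: "U", MISSING: "."}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceSequence:
    """Plus-strand genomic reference for one amplicon."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    tss: int  # 1-based genomic coordinate of the transcription start site
    bases: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.bases):
            raise ValueError(
                f"length mismatch: interval {self.chrom}:{self.start}-{self.end} "
                f"spans {self.end - self.start + 1} bases but sequence has {len(self.bases)}"
            )
        if self.strand != "+":
            raise ValueError("only plus-strand references are supported")
        bad = set(self.bases.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid bases in reference: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class CpGSite:
    """One CpG dinucleotide, addressed by its cytosine."""

    tss_offset: int
    genomic_coord: int  # 1-based coordinate of the C
    index_in_ref: int  # 0-based position within the reference string


@dataclass(frozen=True)
class BisulfiteRead:
    read_id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"empty read {self.read_id!r}")
        bad = set(self.bases.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid bases in read {self.read_id!r}: {sorted(bad)}")


@dataclass(frozen=True)
class Alignment:
    read_id: str
    offset: int | None  # 0-based template offset; None when unaligned
    mismatches: int | None
    reverse_complemented: bool
    aligned: bool
    reason: str = ""


def genomic_to_tss_offset(coord: int, tss: int) -> int:
    """Signed TSS-relative offset: negative upstream, 0 at the TSS itself.

    The mapping is the plain difference ``coord - tss`` on the plus strand,
    so it is its own inverse (see :func:`tss_offset_to_genomic`) and has no
    zero-ambiguity: the TSS maps to 0 (conventionally reported as +1).
    """
    return coord - tss


def tss_offset_to_genomic(offset: int, tss: int) -> int:
    return tss + offset


def find_cpg_sites(ref: ReferenceSequence) -> list[CpGSite]:
    """All CG dinucleotides of the reference, ascending by position."""
    seq = ref.bases.upper()
    sites = []
    i = seq.find("CG")
    while i != -1:
        coord = ref.start + i
        sites.append(
            CpGSite(
                tss_offset=genomic_to_tss_offset(coord, ref.tss),
                genomic_coord=coord,
                index_in_ref=i,
            )
        )
        i = seq.find("CG", i + 1)
    return sites


def convert_reference(ref: ReferenceSequence) -> str:
    """In-silico bisulfite conversion of the reference top strand.

    Non-CpG cytosines become T (fully converted); CpG cytosines become the
    pyrimidine ambiguity symbol ``Y``, which matches either C (methylated)
    or T (unmethylated) during alignment.  All other bases are unchanged.
    """
    seq = ref.bases.upper()
    out = []
    n = len(seq)
    for i, b in enumerate(seq):
        if b == "C":
            out.append("Y" if i + 1 < n and seq[i + 1] == "G" else "T")
        else:
            out.append(b)
    return "".join(out)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


_Y, _C, _T, _N = (ord(c) for c in "YCTN")


def _mismatch_counts(template: np.ndarray, read: np.ndarray) -> np.ndarray:
    """Mismatch count of the read at every ungapped template offset."""
    n_off = len(template) - len(read) + 1
    counts = np.empty(n_off, dtype=int)
    is_y = template == _Y
    for off in range(n_off):
        t = template[off : off + len(read)]
        y = is_y[off : off + len(read)]
        mism = (t != read) & ~(y & ((read == _C) | (read == _T)))
        counts[off] = int(np.count_nonzero(mism))
    return counts


def align_read(
    read: BisulfiteRead,
    template: str,
    max_mismatch_frac: float = 0.05,
    try_reverse_complement: bool = True,
) -> Alignment:
    """Best ungapped placement of a read on the converted template.

    The best offset minimizes the mismatch count; ``Y`` template positions
    match C or T free of penalty.  Ties go to the smallest offset, and when
    both orientations are tried the forward orientation wins ties.  The
    alignment is accepted iff mismatches / read length <= max_mismatch_frac.
    """
    if len(read.bases) > len(template):
        return Alignment(read.read_id, None, None, False, False, "read longer than template")

    tarr = _encode(template)
    candidates = [(read.bases, False)]
    if try_reverse_complement:
        candidates.append((reverse_complement(read.bases), True))

    best: tuple[int, int, bool] | None = None  # (mismatches, offset, is_rc)
    for seq, is_rc in candidates:
        counts = _mismatch_counts(tarr, _encode(seq))
        off = int(np.argmin(counts))  # argmin takes the first (smallest) offset on ties
        key = (int(counts[off]), off, is_rc)
        if best is None or key < best:
            best = key
    mism, off, is_rc = best
    frac = mism / len(read.bases)
    if frac > max_mismatch_frac:
        return Alignment(
            read.read_id, None, None, is_rc, False,
            f"mismatch fraction {frac:.3f} exceeds {max_mismatch_frac}",
        )
    return Alignment(read.read_id, off, mism, is_rc, True)


@dataclass
class MethylationCallMatrix:
    """Per-read (rows) x per-CpG-site (columns) methylation calls.

    ``calls`` holds 1 (methylated, read C), 0 (unmethylated, read T) and
    -1 (missing: site not covered, or an unexpected base).
    ``conversion_rates`` is the per-read fraction of covered non-CpG
    reference cytosines read as T — the bisulfite-conversion QC metric.
    """

    read_ids: list[str]
    sites: list[CpGSite]
    calls: np.ndarray  # int8, shape (n_reads, n_sites)
    conversion_rates: np.ndarray  # float, shape (n_reads,)
    alignments: list[Alignment] = field(default_factory=list)
    n_unaligned: int = 0

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.read_ids), len(self.sites)):
            raise ValueError("calls shape does not match read/site counts")
        if np.any((self.conversion_rates < 0) & ~np.isnan(self.conversion_rates)) or np.any(
            (self.conversion_rates > 1) & ~np.isnan(self.conversion_rates)
        ):
            raise ValueError("conversion rates must lie in [0,1]")

    def to_frame(self) -> pd.DataFrame:
        """Symbolic M/U/. matrix, one row per read — a text lollipop plot."""
        sym = np.vectorize(CALL_SYMBOLS.get)(self.calls)
        return pd.DataFrame(
            sym, index=self.read_ids, columns=[s.tss_offset for s in self.sites]
        )


def call_methylation(
    reads: list[BisulfiteRead],
    ref: ReferenceSequence,
    sites: list[CpGSite] | None = None,
    max_mismatch_frac: float = 0.05,
) -> MethylationCallMatrix:
    """Align reads to the converted reference and call every CpG site.

    For each aligned read and each site it covers, the base over the CpG
    cytosine yields the call: C -> methylated, T -> unmethylated, anything
    else (or an uncovered site) -> missing.  Reads that fail alignment are
    dropped (counted in ``n_unaligned``); zero aligned reads is an error.
    """
    if sites is None:
        sites = find_cpg_sites(ref)
    template = convert_reference(ref)

    ref_seq = ref.bases.upper()
    site_idx = {s.index_in_ref for s in sites}
    # non-CpG reference cytosines, for the conversion-rate denominator
    nonsite_c = np.array(
        [i for i, b in enumerate(ref_seq) if b == "C" and i not in site_idx], dtype=int
    )

    kept_ids: list[str] = []
    rows: list[np.ndarray] = []
    conv: list[float] = []
    alignments: list[Alignment] = []
    n_unaligned = 0

    for read in reads:
        aln = align_read(read, template, max_mismatch_frac)
        alignments.append(aln)
        if not aln.aligned:
            n_unaligned += 1
            continue
        seq = reverse_complement(read.bases) if aln.reverse_complemented else read.bases
        seq = seq.upper()
        lo, hi = aln.offset, aln.offset + len(seq)  # covered template interval

        row = np.full(len(sites), MISSING, dtype=np.int8)
        for j, site in enumerate(sites):
            if lo <= site.index_in_ref < hi:
                base = seq[site.index_in_ref - lo]
                if base == "C":
                    row[j] = METHYLATED
                elif base == "T":
                    row[j] = UNMETHYLATED
        rows.append(row)

        covered = nonsite_c[(nonsite_c >= lo) & (nonsite_c < hi)]
        if covered.size:
            bases = np.array([seq[i - lo] for i in covered])
            n_t = int(np.sum(bases == "T"))
            n_c = int(np.sum(bases == "C"))
            conv.append(n_t / (n_t + n_c) if n_t + n_c else np.nan)
        else:
            conv.append(np.nan)
        kept_ids.append(read.read_id)

    if not kept_ids:
        raise ValueError("no reads aligned to the converted reference")

    return MethylationCallMatrix(
        read_ids=kept_ids,
        sites=list(sites),
        calls=np.vstack(rows),
        conversion_rates=np.asarray(conv, dtype=float),
        alignments=alignments,
        n_unaligned=n_unaligned,
    )


def site_summary(
    matrix: MethylationCallMatrix, min_conversion: float = 0.0
) -> pd.DataFrame:
    """Per-site methylation counts and percentages.

    Reads whose conversion rate falls below ``min_conversion`` are excluded
    (incompletely converted DNA inflates apparent methylation); the default
    0 keeps every read.  Missing cells count toward neither channel; a site
    with zero informative calls reports a missing percentage.

    Columns: ``tss_offset, genomic_coord, n_meth, n_unmeth, n_missing,
    percent_methylation``.
    """
    if not matrix.read_ids:
        raise ValueError("empty call matrix")
    keep = np.ones(len(matrix.read_ids), dtype=bool)
    if min_conversion > 0:
        rates = matrix.conversion_rates
        keep = np.isnan(rates) | (rates >= min_conversion)
    calls = matrix.calls[keep]

    n_meth = np.sum(calls == METHYLATED, axis=0)
    n_unmeth = np.sum(calls == UNMETHYLATED, axis=0)
    n_missing = np.sum(calls == MISSING, axis=0)
    informative = n_meth + n_unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(informative > 0, 100.0 * n_meth / np.maximum(informative, 1), np.nan)

    return pd.DataFrame(
        {
            "tss_offset": [s.tss_offset for s in matrix.sites],
            "genomic_coord": [s.genomic_coord for s in matrix.sites],
            "n_meth": n_meth.astype(int),
            "n_unmeth": n_unmeth.astype(int),
            "n_missing": n_missing.astype(int),
            "percent_methylation": pct,
        }
    )


def sites_to_bed(sites: list[CpGSite], ref: ReferenceSequence) -> pd.DataFrame:
    """CpG sites as 0-based half-open BED intervals over the C base."""
    return pd.DataFrame(
        {
            "chrom": ref.chrom,
            "start": [s.genomic_coord - 1 for s in sites],
            "end": [s.genomic_coord for s in sites],
            "name": [f"CpG_{s.tss_offset}" for s in sites],
        }
    )
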