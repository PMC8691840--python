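"""Naive seed-and-extend read placement and SAM ingestion.

Real libraries enter the pipeline as SAM produced by a production aligner;
the built-in mapper exists so the synthetic path has no external
dependency.  It is an exact k-mer seed + ungapped extension scheme suited
to low-error simulated reads: a read whose 3' or 5' portion crosses a
junction absent from the reference is soft-clipped at the junction, which
is exactly the split-read signal the integration caller consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from .seq import revcomp


@dataclass
class MateAlignment:
    contig: str | None
    pos: int          # 0-based leftmost aligned reference position
    strand: str
    cigar: str
    mapq: int
    nm: int
    read_len: int
    clip_left: int
    clip_right: int
    seq: str = ""

    @property
    def aligned_len(self) -> int:
        return self.read_len - self.clip_left - self.clip_right

    @property
    def end(self) -> int:
        """0-based exclusive end of the aligned segment on the reference."""
        return self.pos + self.aligned_len

    @property
    def mapped(self) -> bool:
        return self.contig is not None


@dataclass
class PairAlignment:
    read_id: str
    mate1: MateAlignment
    mate2: MateAlignment
    is_proper: bool


UNMAPPED = MateAlignment(None, -1, ".", "*", 0, 0, 0, 0, 0)


class KmerIndex:
    """Exact k-mer -> (contig, position) lookup over a set of contigs."""

    def __init__(self, contigs: dict[str, str], k: int = 31):
        self.k = k
        self.contigs = contigs
        self._bytes = {n: np.frombuffer(s.encode(), dtype=np.uint8)
                       for n, s in contigs.items()}
        index: dict[str, list[tuple[str, int]]] = {}
        for name in sorted(contigs):
            s = contigs[name]
            for i in range(len(s) - k + 1):
                index.setdefault(s[i:i + k], []).append((name, i))
        self._index = index

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


# dense-mismatch rule: two mismatches within this many bases mark the start
# of a clipped (junction/foreign) segment rather than sequencing errors
DENSE_GAP = 8


def _trim(neq_idx: np.ndarray, read_len: int, seed_start: int,
          seed_end: int) -> tuple[int, int, int]:
    """Aligned read interval [a, b) around an exactly matching seed.

    Isolated mismatches are tolerated as sequencing errors; a pair of
    mismatches within DENSE_GAP bases marks junction noise and everything
    beyond it (away from the seed) is clipped.  Returns (a, b, n_mismatch
    inside [a, b)).
    """
    if neq_idx.size == 0:
        return 0, read_len, 0
    a, b = 0, read_len
    left = neq_idx[neq_idx < seed_start]
    for j in range(left.size - 1, -1, -1):
        if j > 0 and left[j] - left[j - 1] <= DENSE_GAP:
            a = int(left[j])
            break
    right = neq_idx[neq_idx >= seed_end]
    for j in range(right.size):
        if j + 1 < right.size and right[j + 1] - right[j] <= DENSE_GAP:
            b = int(right[j])
            break
    nm = int(((neq_idx >= a) & (neq_idx < b)).sum())
    return a, b, nm


def _align_candidate(read_arr: np.ndarray, ref_arr: np.ndarray,
                     cand_pos: int, seed_off: int, k: int):
    """Score one candidate placement; returns (score, a, b, nm, pos0).

    ``cand_pos`` is the would-be reference position of read base 0 (may be
    negative or run past the contig end, in which case the overhang is
    clipped).
    """
    L = read_arr.size
    lo = max(0, -cand_pos)
    hi = min(L, ref_arr.size - cand_pos)
    if hi - lo < k:
        return None
    seg = ref_arr[cand_pos + lo:cand_pos + hi]
    sub = read_arr[lo:hi]
    if sub.size == seg.size and (sub == seg).all():
        a, b, nm = lo, hi, 0
    else:
        neq_idx = np.flatnonzero(sub != seg) + lo
        a, b, nm = _trim(neq_idx, L, seed_off, seed_off + k)
        a, b = max(a, lo), min(b, hi)
    score = (b - a) - 3 * nm
    return score, a, b, nm, cand_pos


def map_read(seq: str, index: KmerIndex, max_seed_tries: int = 4):
    """Best placement of one read; returns MateAlignment (possibly UNMAPPED)."""
    k = index.k
    L = len(seq)
    if L < k:
        return UNMAPPED
    best = None
    best_key = None
    n_best_ties = 0
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        offsets = list(range(0, L - k + 1, k))[:max_seed_tries - 1]
        last = L - k
        if last not in offsets:
            offsets.append(last)
        seen: set[tuple[str, int]] = set()
        for off in offsets:
            for contig, pos in index.lookup(s[off:off + k]):
                key = (contig, pos - off)
                if key in seen:
                    continue
                seen.add(key)
                res = _align_candidate(arr, index._bytes[contig], pos - off, off, k)
                if res is None:
                    continue
                score, a, b, nm, pos0 = res
                cand_key = (-score, contig, pos0 + a, 0 if strand == "+" else 1)
                if best_key is None or cand_key < best_key:
                    if best_key is not None and cand_key[0] == best_key[0]:
                        n_best_ties += 1
                    else:
                        n_best_ties = 0
                    best_key = cand_key
                    best = (strand, contig, pos0, a, b, nm, s)
                elif best_key is not None and cand_key[0] == best_key[0]:
                    n_best_ties += 1
    if best is None:
        return UNMAPPED
    strand, contig, pos0, a, b, nm, s = best
    cig = ""
    if a:
        cig += f"{a}S"
    cig += f"{b - a}M"
    if L - b:
        cig += f"{L - b}S"
    mapq = 60 if n_best_ties == 0 else 0
    return MateAlignment(contig=contig, pos=pos0 + a, strand=strand,
                         cigar=cig, mapq=mapq, nm=nm, read_len=L,
                         clip_left=a, clip_right=L - b, seq=s)


def map_pairs(pairs, ref_contigs: dict[str, str], k: int = 31,
              insert_mean: float = 400.0, insert_sd: float = 40.0
              ) -> list[PairAlignment]:
    """Map simulated read pairs against host+insert contigs.

    ``pairs`` is a sequence of objects with name/seq1/seq2 (the read
    simulator's output).  Deterministic given input order.
    """
    index = KmerIndex(ref_contigs, k=k)
    out = []
    lim = insert_mean + 4 * insert_sd
    for rp in pairs:
        m1 = map_read(rp.seq1, index)
        m2 = map_read(rp.seq2, index)
        proper = (m1.mapped and m2.mapped and m1.contig == m2.contig
                  and m1.strand != m2.strand
                  and abs(max(m1.end, m2.end) - min(m1.pos, m2.pos)) <= lim)
        out.append(PairAlignment(rp.name, m1, m2, proper))
    return out


# ---------------------------------------------------------------------------
# SAM I/O (real-data path)

def read_sam_pairs(path: str) -> list[PairAlignment]:
    """Load primary alignments from a SAM/BAM file and pair mates by name.

    Only the fields the caller needs are retained (contig, position,
    strand, CIGAR, MAPQ, clips); unpaired or secondary records are dropped.
    """
    by_name: dict[str, list[MateAlignment]] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_unmapped:
                mate = UNMAPPED
            else:
                clip_l = rec.cigartuples[0][1] if rec.cigartuples[0][0] in (4, 5) else 0
                clip_r = rec.cigartuples[-1][1] if rec.cigartuples[-1][0] in (4, 5) else 0
                rl = rec.infer_read_length() or (rec.query_length or 0)
                mate = MateAlignment(
                    contig=rec.reference_name, pos=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    cigar=rec.cigarstring or "*", mapq=rec.mapping_quality,
                    nm=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                    read_len=rl, clip_left=clip_l, clip_right=clip_r,
                    seq=rec.query_sequence or "")
            by_name.setdefault(rec.query_name, []).append(mate)
    out = []
    for name in sorted(by_name):
        mates = by_name[name]
        if len(mates) == 2:
            m1, m2 = mates
            proper = (m1.mapped and m2.mapped and m1.contig == m2.contig
                      and m1.strand != m2.strand)
            out.append(PairAlignment(name, m1, m2, proper))
    return out


def write_sam(alignments: list[PairAlignment], ref_contigs: dict[str, str],
              path: str) -> None:
    """Write pair alignments as plain SAM (synthetic-path provenance)."""
    names = sorted(ref_contigs)
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": n, "LN": len(ref_contigs[n])} for n in names]}
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for pa in alignments:
            for i, (mate, other) in enumerate(((pa.mate1, pa.mate2),
                                               (pa.mate2, pa.mate1))):
                rec = pysam.AlignedSegment(fh.header)
                rec.query_name = pa.read_id
                flag = 1 | (64 if i == 0 else 128)
                if not mate.mapped:
                    flag |= 4
                else:
                    if mate.strand == "-":
                        flag |= 16
                    if pa.is_proper:
                        flag |= 2
                if other.mapped and other.strand == "-":
                    flag |= 32
                if not other.mapped:
                    flag |= 8
                rec.flag = flag
                if mate.mapped:
                    rec.reference_id = tid[mate.contig]
                    rec.reference_start = mate.pos
                    rec.mapping_quality = mate.mapq
                    rec.cigarstring = mate.cigar
                    rec.set_tag("NM", mate.nm)
                if other.mapped:
                    rec.next_reference_id = tid[other.contig]
                    rec.next_reference_start = other.pos
                if mate.seq:
                    seq = mate.seq
                    rec.query_sequence = seq
                    rec.query_qualities = pysam.qualitystring_to_array("F" * len(seq))
                fh.write(rec)
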