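"""Classification of Sanger-sequenced knock-in junctions.

An observed junction read is aligned (semi-global: free end gaps on the
expected allele, so flanking context beyond the read does not count as an
edit) against the expected HDR allele.  Extra sequence in the observed
read is tested for exact identity to a substring of a homology arm — the
characteristic imperfect-repair signature is a partial duplication of an
arm, optionally with a short filler insertion — and reported with its
position relative to the nearest coding feature (start or stop codon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

MIN_DUP_LEN = 8  # shortest arm substring accepted as a duplication
ARM_SEARCH_WINDOW = 60  # fallback search span around the edit when arms unknown


class JunctionCoverageError(ValueError):
    pass


@dataclass
class JunctionCall:
    status: str  # precise | partial_duplication | small_insertion | deletion | complex
    dup_len: int = 0
    dup_seq: str = ""
    ins_seq: str = ""
    del_len: int = 0
    n_mismatches: int = 0
    offset_from_feature: int | None = None
    coding_affected: bool = False
    edits: list = field(default_factory=list)


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -1
    # observed reads cover only a window of the expected allele: the
    # uncovered expected flanks (end gaps in the observed row) are free
    a.open_end_deletion_score = 0
    a.extend_end_deletion_score = 0
    return a


def _longest_common_substring(s: str, t: str) -> str:
    """Longest exact common substring (first occurrence on ties)."""
    if not s or not t:
        return ""
    best = ""
    # dynamic programming over the shorter string as columns
    prev = [0] * (len(t) + 1)
    for i in range(1, len(s) + 1):
        cur = [0] * (len(t) + 1)
        for j in range(1, len(t) + 1):
            if s[i - 1] == t[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > len(best):
                    best = s[i - cur[j]:i]
        prev = cur
    return best


def classify_junction(observed: str, expected: str,
                      wild_type: str | None = None,
                      feature_anchor: int | None = None,
                      coding_interval: tuple[int, int] | None = None,
                      arms: tuple[str, str] | None = None,
                      min_span: int = 40) -> JunctionCall:
    """Classify one observed junction sequence against the expected allele.

    ``feature_anchor``: 0-based coordinate in ``expected`` of the relevant
    coding-feature edge (first base of the start codon, or first base after
    the stop codon); edit offsets are reported relative to it, negative
    upstream.  ``coding_interval``: [lo, hi) of the coding sequence in
    expected coordinates, used for the coding_affected flag.  ``arms``:
    the homology arms to test duplications against; if absent, a window of
    +/-60 bp around the edit in ``expected`` is used.
    """
    observed = observed.upper()
    expected = expected.upper()
    if len(observed) < min_span:
        raise JunctionCoverageError(
            f"observed sequence ({len(observed)} nt) shorter than the "
            f"required junction span ({min_span} nt)")
    aln = _aligner().align(expected, observed)[0]
    tgt_blocks, qry_blocks = aln.aligned
    edits = []  # (kind, exp_pos, seq_or_len)
    mismatch_pos = []
    for (tb, qb) in zip(tgt_blocks, qry_blocks):
        tseq = expected[tb[0]:tb[1]]
        qseq = observed[qb[0]:qb[1]]
        mismatch_pos.extend(tb[0] + k for k, (x, y) in enumerate(zip(tseq, qseq))
                            if x != y)
    n_mismatch = len(mismatch_pos)
    for i in range(1, len(tgt_blocks)):
        t_gap = tgt_blocks[i][0] - tgt_blocks[i - 1][1]
        q_gap = qry_blocks[i][0] - qry_blocks[i - 1][1]
        pos = int(tgt_blocks[i - 1][1])
        if q_gap > 0:
            edits.append(("ins", pos, observed[qry_blocks[i - 1][1]:qry_blocks[i][0]]))
        if t_gap > 0:
            edits.append(("del", pos, t_gap))

    if not edits and n_mismatch == 0:
        return JunctionCall("precise", n_mismatches=0,
                            offset_from_feature=None, coding_affected=False)

    call = JunctionCall("complex", n_mismatches=n_mismatch, edits=edits)
    ins_edits = [e for e in edits if e[0] == "ins"]
    del_edits = [e for e in edits if e[0] == "del"]
    first = edits[0] if edits else None
    if first is not None and feature_anchor is not None:
        call.offset_from_feature = first[1] - feature_anchor
    call.coding_affected = _coding_affected(edits, coding_interval,
                                            mismatch_pos)

    if len(ins_edits) == 1 and not del_edits:
        _, pos, ins = ins_edits[0]
        if arms is not None:
            search = arms[0] + "#" + arms[1]
        else:
            search = expected[max(0, pos - ARM_SEARCH_WINDOW):pos + ARM_SEARCH_WINDOW]
        dup = _longest_common_substring(ins, search)
        if len(dup) >= MIN_DUP_LEN:
            call.status = "partial_duplication"
            call.dup_len = len(dup)
            call.dup_seq = dup
            i = ins.find(dup)
            call.ins_seq = ins[:i] + ins[i + len(dup):]
        else:
            call.status = "small_insertion"
            call.ins_seq = ins
    elif del_edits and not ins_edits:
        call.status = "deletion"
        call.del_len = sum(e[2] for e in del_edits)
    return call


def _coding_affected(edits, coding_interval, mismatch_pos) -> bool:
    if coding_interval is None:
        return bool(mismatch_pos) or any(e[0] == "del" for e in edits)
    lo, hi = coding_interval
    if any(lo <= p < hi for p in mismatch_pos):
        return True
    for kind, pos, payload in edits:
        if kind == "ins" and lo < pos < hi:
            return True
        if kind == "del" and pos < hi and pos + payload > lo:
            return True
    return False
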