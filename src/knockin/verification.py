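"""Integration-site discovery and copy-number assessment.

The strategy mirrors how knock-in lines are validated by whole-genome
sequencing: align reads against the host genome augmented with the known
insert (tag) sequences, keep read pairs with exactly one mate on an insert
contig (anchor pairs — the paired-end signature of an integration
junction), cluster their host-side positions per junction side, pair a
left with a right cluster into an integration call, refine the coordinate
with soft-clipped (split) reads, and classify copy number from the
insert-to-host depth ratio (a pooled-heterozygote single copy sits near
0.5; tandem concatemers push the ratio above 1).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .mapper import PairAlignment

DEFAULT_CLUSTER_WINDOW = 500
DEFAULT_PAIRING_WINDOW = 1000
DEFAULT_MIN_SUPPORT = 3
DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_CLIP = 8

# depth_ratio bands around the 0.5 heterozygous expectation
SINGLE_COPY_BAND = (0.25, 0.75)


class VerificationError(ValueError):
    pass


@dataclass
class AugmentedReference:
    """Host genome plus known insert (tag) contigs, names disjoint."""
    host_contigs: dict[str, str]
    insert_contigs: dict[str, str]

    def __post_init__(self):
        overlap = set(self.host_contigs) & set(self.insert_contigs)
        if overlap:
            raise VerificationError(f"duplicate contig names: {sorted(overlap)}")

    @property
    def contigs(self) -> dict[str, str]:
        return {**self.host_contigs, **self.insert_contigs}

    def is_insert(self, contig: str) -> bool:
        if contig in self.insert_contigs:
            return True
        if contig in self.host_contigs:
            return False
        raise VerificationError(f"unknown contig {contig!r}")


def augment_reference(host: dict[str, str], inserts: dict[str, str]) -> AugmentedReference:
    return AugmentedReference(dict(host), dict(inserts))


@dataclass(frozen=True)
class AnchorPair:
    read_id: str
    insert_name: str
    insert_pos: int
    host_contig: str
    host_pos: int  # junction-proximal end of the host mate (0-based)
    host_strand: str
    side: str  # "left": host mate upstream of junction; "right": downstream


@dataclass
class BreakpointCluster:
    insert_name: str
    host_contig: str
    lo: int
    hi: int  # half-open
    side: str
    support: int
    member_ids: list[str]

    @property
    def innermost(self) -> int:
        """Cluster bound closest to the putative junction."""
        return self.hi - 1 if self.side == "left" else self.lo


@dataclass
class IntegrationCall:
    insert_name: str
    host_contig: str
    coordinate: int  # 1-based left-junction base
    left_support: int
    right_support: int
    split_support: int
    copy_class: str = "unassessed"
    depth_ratio: float = float("nan")
    one_sided: bool = False


def collect_anchor_pairs(alignments: list[PairAlignment],
                         ref: AugmentedReference,
                         min_mapq: int = DEFAULT_MIN_MAPQ) -> list[AnchorPair]:
    """Pairs with exactly one mate on an insert contig (one-insert-mate XOR).

    The host-side junction side follows from the host mate's orientation: a
    forward host mate points rightwards into the junction (side "left"), a
    reverse mate leftwards (side "right").
    """
    out = []
    for pa in alignments:
        m1, m2 = pa.mate1, pa.mate2
        if not (m1.mapped and m2.mapped):
            continue
        if min(m1.mapq, m2.mapq) < min_mapq:
            continue
        on_insert = (ref.is_insert(m1.contig), ref.is_insert(m2.contig))
        if on_insert[0] == on_insert[1]:
            continue  # both-host or both-insert
        host, ins = (m2, m1) if on_insert[0] else (m1, m2)
        side = "left" if host.strand == "+" else "right"
        host_pos = host.end if side == "left" else host.pos
        out.append(AnchorPair(pa.read_id, ins.contig, ins.pos, host.contig,
                              host_pos, host.strand, side))
    return out


def cluster_anchors(anchors: list[AnchorPair],
                    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
                    min_support: int = DEFAULT_MIN_SUPPORT
                    ) -> tuple[list[BreakpointCluster], list[BreakpointCluster]]:
    """Single-linkage clustering of anchor host positions per
    (insert, contig, side) with gap <= cluster_window.

    Returns (clusters, low_support): clusters below ``min_support`` are not
    called but surfaced as diagnostics — a weakly supported signal is
    reported, not silently decided either way.
    """
    if cluster_window <= 0:
        raise VerificationError("cluster_window must be positive")
    groups: dict[tuple[str, str, str], list[AnchorPair]] = {}
    for a in anchors:
        groups.setdefault((a.insert_name, a.host_contig, a.side), []).append(a)
    kept: list[BreakpointCluster] = []
    low: list[BreakpointCluster] = []
    for (ins, contig, side), members in groups.items():
        members.sort(key=lambda a: a.host_pos)
        run: list[AnchorPair] = []
        for a in members:
            if run and a.host_pos - run[-1].host_pos > cluster_window:
                _emit(run, ins, contig, side, min_support, kept, low)
                run = []
            run.append(a)
        if run:
            _emit(run, ins, contig, side, min_support, kept, low)
    order = {"left": 0, "right": 1}
    for lst in (kept, low):
        lst.sort(key=lambda c: (c.host_contig, c.lo, order[c.side]))
    return kept, low


def _emit(run, ins, contig, side, min_support, kept, low):
    c = BreakpointCluster(ins, contig, run[0].host_pos,
                          run[-1].host_pos + 1, side, len(run),
                          [a.read_id for a in run])
    (kept if c.support >= min_support else low).append(c)


def collect_split_boundaries(alignments: list[PairAlignment],
                             ref: AugmentedReference,
                             min_clip: int = DEFAULT_MIN_CLIP,
                             min_mapq: int = DEFAULT_MIN_MAPQ,
                             probe_len: int = 20) -> dict[str, list[int]]:
    """Soft-clip boundaries of host-mapped mates, per host contig.

    A mate clipped on one side marks a reference discontinuity; at a true
    insertion junction these boundaries pile up on the junction base.
    When the junction carries microhomology (the insert terminus happens to
    match the adjacent host bases) the aligner over-extends into the insert
    by the homologous length, shifting the raw boundary.  Each clipped
    segment is therefore located within the known insert sequences and the
    boundary corrected by the over-extension, so boundaries from both
    junction sides agree on the exact left-junction base.  Returned
    positions are 0-based counts of host bases left of the junction.
    """
    inserts = ref.insert_contigs
    out: dict[str, list[int]] = {}
    for pa in alignments:
        for mate in (pa.mate1, pa.mate2):
            if not mate.mapped or mate.mapq < min_mapq:
                continue
            if ref.is_insert(mate.contig):
                continue
            L = mate.read_len
            if mate.clip_right >= min_clip:
                b = mate.end
                if mate.seq:
                    clip = mate.seq[L - mate.clip_right:]
                    probe = clip[:probe_len]
                    t = _unique_find(inserts, probe)
                    if t is not None:
                        b -= t  # aligner consumed t insert bases as host
                out.setdefault(mate.contig, []).append(b)
            if mate.clip_left >= min_clip:
                b = mate.pos
                if mate.seq:
                    clip = mate.seq[:mate.clip_left]
                    probe = clip[-probe_len:]
                    hit = _unique_find(inserts, probe, end_offset=True)
                    if hit is not None:
                        b += hit  # insert-end bases consumed as host
                out.setdefault(mate.contig, []).append(b)
    return out


def _unique_find(inserts: dict[str, str], probe: str,
                 end_offset: bool = False) -> int | None:
    """Offset of a uniquely matching probe within any insert contig.

    Returns the probe's start offset (or, with ``end_offset``, the distance
    from the probe's end to the insert's end); None if the probe is absent
    or ambiguous.
    """
    if len(probe) < 8:
        return None
    best = None
    for name in sorted(inserts):
        seq = inserts[name]
        pos = seq.find(probe)
        if pos < 0:
            continue
        if seq.find(probe, pos + 1) >= 0 or best is not None:
            return None  # ambiguous within or across inserts
        best = len(seq) - (pos + len(probe)) if end_offset else pos
    return best


def call_integrations(clusters: list[BreakpointCluster],
                      split_boundaries: dict[str, list[int]] | None = None,
                      pairing_window: int = DEFAULT_PAIRING_WINDOW
                      ) -> list[IntegrationCall]:
    """Pair left/right breakpoint clusters into integration calls.

    The coordinate is the 1-based left-junction base: the modal split-read
    boundary when any split read supports the junction, otherwise the
    midpoint between the innermost left/right anchor bounds.  Unpaired
    clusters still produce a call, flagged one-sided.
    """
    split_boundaries = split_boundaries or {}
    lefts = [c for c in clusters if c.side == "left"]
    rights = [c for c in clusters if c.side == "right"]
    used_right: set[int] = set()
    calls: list[IntegrationCall] = []
    for lc in lefts:
        best_j = None
        best_gap = None
        for j, rc in enumerate(rights):
            if j in used_right:
                continue
            if rc.insert_name != lc.insert_name or rc.host_contig != lc.host_contig:
                continue
            gap = abs(rc.innermost - lc.innermost)
            if gap <= pairing_window and (best_gap is None or gap < best_gap):
                best_gap, best_j = gap, j
        if best_j is None:
            calls.append(_one_sided_call(lc, split_boundaries))
            continue
        rc = rights[best_j]
        used_right.add(best_j)
        lo = min(lc.innermost, rc.innermost)
        hi = max(lc.innermost, rc.innermost)
        splits = [b for b in split_boundaries.get(lc.host_contig, [])
                  if lo - pairing_window <= b <= hi + pairing_window]
        if splits:
            coord = Counter(splits).most_common()
            coord.sort(key=lambda kv: (-kv[1], kv[0]))
            coordinate = coord[0][0]  # 0-based boundary == 1-based left base
            split_support = len(splits)
        else:
            coordinate = (lo + hi) // 2
            split_support = 0
        calls.append(IntegrationCall(lc.insert_name, lc.host_contig,
                                     coordinate, lc.support, rc.support,
                                     split_support))
    for j, rc in enumerate(rights):
        if j not in used_right:
            calls.append(_one_sided_call(rc, split_boundaries))
    calls.sort(key=lambda c: (c.host_contig, c.coordinate, c.insert_name))
    return calls


def _one_sided_call(c: BreakpointCluster,
                    split_boundaries: dict[str, list[int]]) -> IntegrationCall:
    splits = [b for b in split_boundaries.get(c.host_contig, [])
              if c.lo - DEFAULT_PAIRING_WINDOW <= b <= c.hi + DEFAULT_PAIRING_WINDOW]
    if splits:
        coord = Counter(splits).most_common()
        coord.sort(key=lambda kv: (-kv[1], kv[0]))
        coordinate, split_support = coord[0][0], len(splits)
    else:
        coordinate, split_support = c.innermost, 0
    left = c.support if c.side == "left" else 0
    right = c.support if c.side == "right" else 0
    return IntegrationCall(c.insert_name, c.host_contig, coordinate,
                           left, right, split_support, one_sided=True)


def contig_depths(alignments: list[PairAlignment],
                  ref: AugmentedReference) -> dict[str, float]:
    """Mean aligned depth per contig (aligned bases / contig length)."""
    bases = Counter()
    for pa in alignments:
        for mate in (pa.mate1, pa.mate2):
            if mate.mapped:
                bases[mate.contig] += mate.aligned_len
    return {name: bases[name] / len(seq)
            for name, seq in ref.contigs.items()}


def assess_copy_number(alignments: list[PairAlignment],
                       call: IntegrationCall, ref: AugmentedReference,
                       bands: tuple[float, float] = SINGLE_COPY_BAND
                       ) -> IntegrationCall:
    """Attach depth_ratio and copy class to a call.

    depth_ratio = mean insert-contig depth / mean host depth.  A pooled-F1
    heterozygous single copy carries the insert on one haplotype, so the
    expectation is 0.5; ratios above ``bands[1]`` indicate multiple copies
    or a concatemer, below ``bands[0]`` a partial/low-support event.
    """
    depths = contig_depths(alignments, ref)
    host = [depths[c] for c in ref.host_contigs]
    host_mean = sum(host) / len(host)
    if host_mean == 0:
        raise VerificationError("zero host depth; cannot form depth ratio")
    ratio = depths.get(call.insert_name, 0.0) / host_mean
    lo, hi = bands
    if ratio > hi:
        cls = "multi_copy_or_concatemer"
    elif ratio >= lo:
        cls = "single_copy_het"
    else:
        cls = "partial_low_support"
    call.depth_ratio = ratio
    call.copy_class = cls
    return call
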