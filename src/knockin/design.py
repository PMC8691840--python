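"""Cloning-free knock-in donor design.

The donor is a PCR product: a fluorophore/tag cassette (ORF stripped of its
start and stop codons so it fuses in frame) flanked by short homology arms
(30-40 bp) that are added as primer tails.  The primers carry 5' biotin to
limit in-vivo concatemerisation.  Genotyping primers sit strictly outside
the donor footprint so the wild-type and knock-in amplicons differ by
exactly the cassette-block length.

All coordinates are 0-based half-open internally; reported coordinates in
output tables are 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

from .seq import (STOP_CODONS, gc_fraction, in_frame_stops, is_dna, revcomp,
                  translate)

#: Mean molar mass of one double-stranded DNA base pair (g/mol/bp).
MEAN_BP_MASS_G_PER_MOL = 650.0

#: SpCas9 blunt-cut offset: 3 bp 5' of the PAM, i.e. after protospacer
#: position 17 (0-based cut coordinate = protospacer_start + 17 on +).
CAS9_CUT_OFFSET = 17

ARM_LEN_MIN = 30
ARM_LEN_MAX = 40


class Terminus(str, Enum):
    N = "N"
    C = "C"


class DesignError(ValueError):
    """Violation of a donor-design constraint (frame, bounds, inputs)."""


@dataclass(frozen=True)
class TargetLocus:
    """A genomic window around the tag insertion junction.

    ``insertion_point`` is the offset within ``window_seq`` of the junction
    between two codons; ``frame_anchor`` is the offset of a codon start
    (e.g. the ATG) so the frame of the junction can be checked.
    """
    contig_id: str
    window_seq: str
    window_start: int  # 0-based start of window on contig
    insertion_point: int  # offset within window
    frame_anchor: int  # offset of a codon boundary (reading-frame start)
    terminus: Terminus
    strand: str = "+"

    def __post_init__(self):
        if not is_dna(self.window_seq):
            raise DesignError("window_seq contains non-IUPAC letters")
        if not 0 <= self.insertion_point <= len(self.window_seq):
            raise DesignError("insertion_point outside window")
        if (self.insertion_point - self.frame_anchor) % 3 != 0:
            raise DesignError(
                "insertion_point is not on a codon boundary relative to "
                f"frame_anchor (offset {self.insertion_point - self.frame_anchor})")
        if self.strand not in "+-":
            raise DesignError("strand must be '+' or '-'")


@dataclass(frozen=True)
class GuideCandidate:
    """A 20-nt SpCas9 protospacer adjacent to an NGG PAM."""
    spacer: str
    pam: str
    strand: str
    cut_site: int  # offset in window coordinates
    distance_to_insertion: int  # signed, cut_site - insertion_point

    def __post_init__(self):
        if len(self.spacer) != 20:
            raise DesignError("spacer must be 20 nt")
        if self.pam[1:3].upper() != "GG":
            raise DesignError("PAM must match NGG")


@dataclass(frozen=True)
class TagCassette:
    """Fluorophore coding sequence with no ATG and no stop codon.

    ``block`` (linker_5 + seq + linker_3) is the unit spliced between the
    homology arms; its length must be a multiple of 3 with no in-frame stop.
    """
    name: str
    seq: str
    linker_5: str = ""
    linker_3: str = ""

    def __post_init__(self):
        if self.seq[:3].upper() == "ATG":
            raise DesignError("cassette seq must not start with ATG")
        if self.seq[-3:].upper() in STOP_CODONS and len(self.seq) % 3 == 0:
            raise DesignError("cassette seq must not end with a stop codon")
        if len(self.block) % 3 != 0:
            raise DesignError("cassette block length not divisible by 3")
        if in_frame_stops(self.block):
            raise DesignError("in-frame stop codon inside cassette block")

    @property
    def block(self) -> str:
        return self.linker_5 + self.seq + self.linker_3


@dataclass(frozen=True)
class PrimerPair:
    fwd_seq: str
    rev_seq: str
    fwd_biotin: bool
    rev_biotin: bool
    purpose: str  # "donor_amplification" | "genotyping"
    predicted_wt_amplicon_bp: int | None = None
    predicted_ki_amplicon_bp: int | None = None


@dataclass(frozen=True)
class DonorDesign:
    left_arm: str
    right_arm: str
    cassette: TagCassette
    donor_seq: str
    primer_fwd: str | None = None
    primer_rev: str | None = None
    mass_conc_ng_per_ul: float | None = None
    molarity_nM: float | None = None

    def __post_init__(self):
        expect = self.left_arm + self.cassette.block + self.right_arm
        if self.donor_seq != expect:
            raise DesignError("donor_seq != left_arm + cassette block + right_arm")


@dataclass(frozen=True)
class MixRecipe:
    """Injection-mix concentrations (metadata; range checks only)."""
    sgRNA_ng_per_ul: float = 17.5
    cas9_mRNA_ng_per_ul: float = 150.0
    donor_ng_per_ul: float = 9.0

    RANGES = {"sgRNA_ng_per_ul": (15.0, 20.0),
              "cas9_mRNA_ng_per_ul": (150.0, 150.0),
              "donor_ng_per_ul": (8.0, 10.0)}

    def in_recommended_range(self) -> dict[str, bool]:
        return {k: lo <= getattr(self, k) <= hi
                for k, (lo, hi) in self.RANGES.items()}


# ---------------------------------------------------------------------------
# guide selection

def cut_site_of(protospacer_start: int, strand: str) -> int:
    """Blunt Cas9 cut coordinate for a protospacer starting at ``protospacer_start``.

    On '+' the protospacer occupies [start, start+20) with the PAM at
    [start+20, start+23); the cut falls between protospacer positions 16 and
    17, i.e. at coordinate start+17.  On '-' the protospacer occupies
    [start, start+20) on the minus strand with the (plus-strand CCN) PAM at
    [start-3, start), mirrored: cut at start+3.
    """
    if strand == "+":
        return protospacer_start + CAS9_CUT_OFFSET
    if strand == "-":
        return protospacer_start + (20 - CAS9_CUT_OFFSET)
    raise DesignError(f"invalid strand {strand!r}")


def find_protospacers(locus: TargetLocus, search_radius: int) -> list[GuideCandidate]:
    """Exhaustively scan both strands for 20-mer+NGG protospacers whose cut
    site lies within ``search_radius`` of the insertion point.

    Returns candidates sorted by |distance to insertion| ascending, ties
    broken by lower cut coordinate then '+' strand.  No off-target or
    activity ranking is attempted.
    """
    if search_radius < 0:
        raise DesignError("search_radius must be >= 0")
    w = locus.window_seq.upper()
    out: list[GuideCandidate] = []
    # plus strand: spacer [s, s+20), PAM [s+20, s+23) == NGG
    for s in range(0, len(w) - 22):
        if w[s + 21:s + 23] == "GG":
            cut = cut_site_of(s, "+")
            d = cut - locus.insertion_point
            if abs(d) <= search_radius:
                out.append(GuideCandidate(w[s:s + 20], w[s + 20:s + 23], "+", cut, d))
        # minus strand: plus-strand CCN at [p, p+3), protospacer [p+3, p+23)
        if w[s:s + 2] == "CC" and s + 23 <= len(w):
            start = s + 3
            cut = start + (20 - CAS9_CUT_OFFSET)
            d = cut - locus.insertion_point
            if abs(d) <= search_radius:
                spacer = revcomp(w[start:start + 20])
                pam = revcomp(w[s:s + 3])
                out.append(GuideCandidate(spacer, pam, "-", cut, d))
    out.sort(key=lambda g: (abs(g.distance_to_insertion), g.cut_site,
                            0 if g.strand == "+" else 1))
    return out


# ---------------------------------------------------------------------------
# donor assembly

def extract_homology_arms(locus: TargetLocus, arm_len: int,
                          arm_len_right: int | None = None) -> tuple[str, str]:
    """Arms immediately flanking the insertion point.

    Lengths outside the recommended 30-40 bp raise a warning but are
    returned anyway (exploration is allowed; the donor invariant is not).
    """
    right_len = arm_len if arm_len_right is None else arm_len_right
    for n in {arm_len, right_len}:
        if not ARM_LEN_MIN <= n <= ARM_LEN_MAX:
            warnings.warn(
                f"homology arm length {n} outside recommended "
                f"{ARM_LEN_MIN}-{ARM_LEN_MAX} bp", UserWarning, stacklevel=2)
    ip = locus.insertion_point
    if ip - arm_len < 0 or ip + right_len > len(locus.window_seq):
        deficit = max(arm_len - ip, ip + right_len - len(locus.window_seq))
        raise DesignError(
            f"arms extend {deficit} bp beyond the locus window; widen the window")
    return (locus.window_seq[ip - arm_len:ip],
            locus.window_seq[ip:ip + right_len])


def build_tag_cassette(raw_orf: str, terminus: Terminus | str = Terminus.C,
                       linker_5: str = "", linker_3: str = "",
                       name: str = "tag") -> TagCassette:
    """Trim a tag ORF for in-frame fusion.

    The leading ATG and trailing stop codon are stripped regardless of
    terminus (knock-in cassettes carry neither); linkers are the caller's
    responsibility and are checked only for frame and stops.
    """
    if len(raw_orf) < 6:
        raise DesignError("ORF too short to trim")
    seq = raw_orf.upper()
    if seq[:3] == "ATG":
        seq = seq[3:]
    if len(seq) % 3 == 0 and seq[-3:] in STOP_CODONS:
        seq = seq[:-3]
    # trailing stop may still be present if the raw ORF had frame slippage
    block = linker_5 + seq + linker_3
    if len(block) % 3 != 0:
        raise DesignError(
            f"cassette block length {len(block)} not divisible by 3")
    stops = in_frame_stops(block)
    if stops:
        raise DesignError(f"in-frame stop codon at block offset {stops[0]}")
    return TagCassette(name=name, seq=seq, linker_5=linker_5, linker_3=linker_3)


def splice_cassette(window_seq: str, insertion_point: int, block: str) -> str:
    """The HDR-edited allele: cassette block inserted at the junction."""
    return window_seq[:insertion_point] + block + window_seq[insertion_point:]


def build_expected_allele(locus: TargetLocus, donor: "DonorDesign | TagCassette | str") -> str:
    """Expected knock-in allele sequence over the locus window."""
    if isinstance(donor, DonorDesign):
        block = donor.cassette.block
    elif isinstance(donor, TagCassette):
        block = donor.block
    else:
        block = donor
    return splice_cassette(locus.window_seq, locus.insertion_point, block)


def assemble_donor(locus: TargetLocus, arms: tuple[str, str],
                   cassette: TagCassette) -> DonorDesign:
    """Concatenate arms and cassette block; verify the edited allele stays
    in frame across both junctions."""
    left, right = arms
    ip = locus.insertion_point
    if locus.window_seq[ip - len(left):ip] != left or \
            locus.window_seq[ip:ip + len(right)] != right:
        raise DesignError("arms do not match the locus at the insertion point")
    donor_seq = left + cassette.block + right
    hdr = splice_cassette(locus.window_seq, ip, cassette.block)
    frame = locus.frame_anchor % 3
    # no stop may appear within the spliced cassette block in the gene frame
    block_lo = ip
    block_hi = ip + len(cassette.block)
    for off in in_frame_stops(hdr, frame):
        if block_lo <= off < block_hi:
            raise DesignError("cassette block introduces an in-frame stop in "
                              "the edited allele")
    return DonorDesign(left_arm=left, right_arm=right, cassette=cassette,
                       donor_seq=donor_seq)


# ---------------------------------------------------------------------------
# primers

def design_donor_primers(donor: DonorDesign,
                         anneal_len_range: tuple[int, int] = (18, 25)) -> PrimerPair:
    """Biotinylated donor-amplification primers: homology-arm tails plus a
    cassette-annealing 3' segment chosen for 40-60% GC."""
    lo, hi = anneal_len_range
    block = donor.cassette.block
    if len(block) < hi:
        hi = len(block)
        if lo > hi:
            raise DesignError("cassette too short for annealing segment")
    k_f = _pick_anneal(lambda k: block[:k], lo, hi)
    k_r = _pick_anneal(lambda k: block[-k:], lo, hi)
    fwd = donor.left_arm + block[:k_f]
    rev = revcomp(block[-k_r:] + donor.right_arm)
    return PrimerPair(fwd_seq=fwd, rev_seq=rev, fwd_biotin=True,
                      rev_biotin=True, purpose="donor_amplification")


def _pick_anneal(segment_of, lo: int, hi: int,
                 gc_lo: float = 0.4, gc_hi: float = 0.6) -> int:
    target = (gc_lo + gc_hi) / 2
    best = None
    for k in range(lo, hi + 1):
        gc = gc_fraction(segment_of(k))
        cost = 0.0 if gc_lo <= gc <= gc_hi else min(abs(gc - gc_lo), abs(gc - gc_hi))
        key = (cost, abs(gc - target), k)
        if best is None or key < best[0]:
            best = (key, k)
    return best[1]


def design_genotyping_primers(locus: TargetLocus, donor: DonorDesign,
                              flank_min: int = 50,
                              primer_len: int = 20) -> PrimerPair:
    """External genotyping primers strictly outside the donor footprint.

    The knock-in amplicon exceeds the wild-type one by exactly the cassette
    block length, so a single PCR genotypes the full insertion.
    """
    ip = locus.insertion_point
    arm_lo = ip - len(donor.left_arm)
    arm_hi = ip + len(donor.right_arm)
    if arm_lo < flank_min or len(locus.window_seq) - arm_hi < flank_min:
        raise DesignError(
            f"window must extend >= {flank_min} bp beyond both homology arms")
    w = locus.window_seq
    # forward primer: best-GC window fully upstream of the left arm
    fwd_start = _pick_external(w, 0, arm_lo - primer_len, primer_len)
    rev_start = _pick_external(w, arm_hi, len(w) - primer_len, primer_len)
    fwd = w[fwd_start:fwd_start + primer_len]
    rev = revcomp(w[rev_start:rev_start + primer_len])
    wt_amp = rev_start + primer_len - fwd_start
    ki_amp = wt_amp + len(donor.cassette.block)
    return PrimerPair(fwd_seq=fwd, rev_seq=rev, fwd_biotin=False,
                      rev_biotin=False, purpose="genotyping",
                      predicted_wt_amplicon_bp=wt_amp,
                      predicted_ki_amplicon_bp=ki_amp)


def _pick_external(w: str, lo: int, hi: int, k: int,
                   gc_lo: float = 0.4, gc_hi: float = 0.6) -> int:
    """Start position in [lo, hi] (inclusive) of the k-mer with GC closest
    to the 40-60% window; prefers positions nearest the donor footprint
    (hi for upstream search windows is closest when searching upstream)."""
    if hi < lo:
        raise DesignError("no room for external primer")
    target = (gc_lo + gc_hi) / 2
    best = None
    for s in range(lo, hi + 1):
        gc = gc_fraction(w[s:s + k])
        cost = 0.0 if gc_lo <= gc <= gc_hi else min(abs(gc - gc_lo), abs(gc - gc_hi))
        key = (cost, abs(gc - target), s)
        if best is None or key < best[0]:
            best = (key, s)
    return best[1]


# ---------------------------------------------------------------------------
# in-silico PCR and molarity

def in_silico_pcr(template: str, fwd: str, rev: str, min_anneal: int = 15) -> str:
    """Predict the product of a PCR with 5'-tailed primers.

    The longest 3'-terminal segment (>= ``min_anneal``) of each primer that
    matches the template exactly defines the annealing site; the product is
    the full forward primer, the template between the annealing sites, and
    the reverse complement of the full reverse primer.
    """
    f_site, f_len = _anneal_site(template, fwd, min_anneal)
    rc = revcomp(template)
    r_site_rc, r_len = _anneal_site(rc, rev, min_anneal)
    r_end = len(template) - r_site_rc  # template coord just past rev anneal start
    tail_f = fwd[:len(fwd) - f_len]
    tail_r = rev[:len(rev) - r_len]
    core = template[f_site:r_end]
    if not core:
        raise DesignError("primers do not define a product on this template")
    return tail_f + core + revcomp(tail_r)


def _anneal_site(template: str, primer: str, min_anneal: int) -> tuple[int, int]:
    """(template position, annealed length) of the longest exact 3'-end match."""
    for k in range(len(primer), min_anneal - 1, -1):
        seg = primer[-k:]
        pos = template.find(seg)
        if pos >= 0:
            if template.find(seg, pos + 1) >= 0:
                raise DesignError("primer annealing site is not unique")
            return pos, k
    raise DesignError("primer does not anneal to template "
                      f"(>= {min_anneal} nt exact 3' match required)")


def donor_molarity(mass_conc_ng_per_ul: float, length_bp: int,
                   bp_mass: float = MEAN_BP_MASS_G_PER_MOL) -> float:
    """Molar concentration (nM) of a dsDNA donor.

    nM = ng/µl × 1e6 / (length × 650 g/mol/bp): ~10 ng/µl of a ~780-bp donor
    is ~20 nM, a large molar excess for its mass.
    """
    if mass_conc_ng_per_ul <= 0 or length_bp <= 0:
        raise DesignError("mass concentration and length must be positive")
    return mass_conc_ng_per_ul * 1e6 / (length_bp * bp_mass)
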