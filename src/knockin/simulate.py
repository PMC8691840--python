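"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators: toy loci with an in-frame ORF, paired-end WGS libraries
from knock-in alleles (single-copy heterozygous, homozygous, or tandem
concatemers), and single-channel nucleus time-lapse movies following the
PCNA dynamics the phase classifier assumes (G1 decay, S rise, late-S
replication-focus speckles, maximal pixel-intensity dispersion at the S/G2
transition, sharp M-phase drop).

Every generator takes an integer seed and is bit-reproducible; the returned
``SimTruth`` carries the full parameter set and the planted ground truth so
downstream modules can be scored without reference to generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seq import STOP_CODONS, revcomp

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimTruth:
    kind: str  # "locus" | "reads" | "movie"
    seed: int
    parameters: dict
    truth: dict


@dataclass
class SimulatedLocus:
    seq: str
    orf_start: int  # 0-based, inclusive (ATG)
    orf_end: int    # 0-based, exclusive (just past the stop codon)
    truth: SimTruth


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p).tobytes().decode()


def simulate_locus(length: int = 2000, gc: float = 0.4, seed: int = 0,
                   orf_frac: float = 0.5) -> SimulatedLocus:
    """Random genomic window containing one in-frame ORF (ATG...stop).

    The ORF occupies ``orf_frac`` of the window, centred; internal in-frame
    stop codons are recoded so the ORF is clean.  Codon boundaries follow
    directly from ``orf_start``.
    """
    rng = np.random.default_rng(seed)
    seq = list(_random_dna(rng, length, gc))
    n_codons = max(3, int(length * orf_frac) // 3)
    orf_start = (length - n_codons * 3) // 2
    orf_end = orf_start + n_codons * 3
    seq[orf_start:orf_start + 3] = "ATG"
    stop = ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
    seq[orf_end - 3:orf_end] = stop
    # recode internal stops (first base swap keeps GC roughly unchanged)
    for i in range(orf_start + 3, orf_end - 3, 3):
        if "".join(seq[i:i + 3]) in STOP_CODONS:
            seq[i] = "C"
    out = "".join(seq)
    truth = SimTruth("locus", seed,
                     {"length": length, "gc": gc, "orf_frac": orf_frac},
                     {"orf_start": orf_start, "orf_end": orf_end})
    return SimulatedLocus(out, orf_start, orf_end, truth)


def plant_insertion(host_seq: str, cassette_block: str, position: int,
                    zygosity: str = "het", tandem_copies: int = 1,
                    seed: int = 0) -> tuple[dict[str, str], SimTruth]:
    """Knock-in allele pair with ``tandem_copies`` cassette blocks spliced
    at ``position`` (0-based: the insert lands between position-1 and
    position).  'het' keeps one wild-type allele; 'hom' edits both.

    The reported 1-based left-junction coordinate equals ``position``
    (the last host base before the insert).
    """
    if not 0 <= position <= len(host_seq):
        raise ValueError("insertion position outside host sequence")
    if tandem_copies < 1:
        raise ValueError("tandem_copies must be >= 1")
    if zygosity not in ("het", "hom"):
        raise ValueError("zygosity must be 'het' or 'hom'")
    edited = host_seq[:position] + cassette_block * tandem_copies + host_seq[position:]
    alleles = {"edited": edited}
    if zygosity == "het":
        alleles["wt"] = host_seq
    else:
        alleles["edited2"] = edited
    truth = SimTruth(
        "locus", seed,
        {"position": position, "zygosity": zygosity,
         "tandem_copies": tandem_copies,
         "cassette_len": len(cassette_block)},
        {"junction_coord_1based": position,
         "left_junction_0based": position,
         "copies": tandem_copies, "zygosity": zygosity})
    return alleles, truth


@dataclass
class ReadPair:
    name: str
    seq1: str
    seq2: str
    allele: str
    frag_start: int
    frag_end: int


def simulate_read_pairs(alleles: dict[str, str], depth: float,
                        read_len: int = 150, insert_mean: float = 400.0,
                        insert_sd: float = 40.0, error_rate: float = 0.001,
                        seed: int = 0) -> tuple[list[ReadPair], SimTruth]:
    """FR paired-end library over a set of alleles.

    ``depth`` is the total locus depth summed across alleles (a
    heterozygote sequenced to 20x contributes ~10x per haplotype, which is
    what makes the insert-contig depth ratio informative about copy
    number).  Fragment lengths are Normal(insert_mean, insert_sd) truncated
    to [read_len, allele length]; substitution errors are i.i.d. at
    ``error_rate`` per base; qualities are constant Q37.
    """
    if insert_mean < read_len:
        raise ValueError("insert_mean must be >= read_len")
    rng = np.random.default_rng(seed)
    pairs: list[ReadPair] = []
    per_allele_depth = depth / len(alleles)
    idx = 0
    for allele_name in sorted(alleles):
        aseq = alleles[allele_name]
        L = len(aseq)
        n_pairs = int(round(per_allele_depth * L / (2 * read_len)))
        frag_len = rng.normal(insert_mean, insert_sd, size=n_pairs)
        frag_len = np.clip(np.rint(frag_len), read_len, L).astype(int)
        starts = rng.integers(0, np.maximum(L - frag_len + 1, 1))
        n_err = rng.binomial(2 * read_len, error_rate, size=n_pairs)
        for j in range(n_pairs):
            s, fl = int(starts[j]), int(frag_len[j])
            frag = aseq[s:s + fl]
            r1 = frag[:read_len]
            r2 = revcomp(frag)[:read_len]
            if n_err[j]:
                merged = list(r1 + r2)
                for p in rng.integers(0, 2 * read_len, size=int(n_err[j])):
                    cur = merged[p]
                    repl = "ACGT"[rng.integers(0, 4)]
                    while repl == cur:
                        repl = "ACGT"[rng.integers(0, 4)]
                    merged[p] = repl
                r1 = "".join(merged[:read_len])
                r2 = "".join(merged[read_len:])
            pairs.append(ReadPair(f"sim_{idx}", r1, r2, allele_name, s, s + fl))
            idx += 1
    truth = SimTruth("reads", seed,
                     {"depth": depth, "read_len": read_len,
                      "insert_mean": insert_mean, "insert_sd": insert_sd,
                      "error_rate": error_rate,
                      "allele_lengths": {k: len(v) for k, v in alleles.items()}},
                     {"n_pairs": len(pairs)})
    return pairs, truth


# ---------------------------------------------------------------------------
# nucleus movies


def default_cycle_schedule() -> list[tuple[str, int]]:
    """Phase schedule of a dividing track at 20-min frames.

    The track starts in S (dividing-cell traces begin with the PCNA rise;
    G1 cells are modelled as separate non-dividing decay tracks): ~7.3 h
    early S, 4 h late S with replication-focus speckles, ~4.3 h G2, 2 h M.
    """
    return [("S", 22), ("lateS", 12), ("G2", 13), ("M", 6)]


def simulate_nucleus_movie(phase_schedule: list[tuple[str, int]] | None = None,
                           img_size: int = 64, roi_radius: int = 16,
                           base_intensity: float = 1000.0,
                           g1_decay: float = 0.02, s_slope: float = 0.02,
                           n_speckles: int = 6, speckle_amp: float = 800.0,
                           m_drop_frac: float = 0.6, m_drop_frames: int = 2,
                           noise_sd: float = 30.0,
                           dispersion_base: float = 40.0,
                           dispersion_peak: float = 180.0,
                           dispersion_fall_frames: int = 8,
                           frame_interval_min: float = 20.0,
                           seed: int = 0):
    """Single-channel nucleus time-lapse with programmed PCNA dynamics.

    The mean ROI intensity decays exponentially in G1 (rate ``g1_decay``
    per frame), rises linearly through S/lateS (``s_slope`` x base per
    frame), plateaus in G2, and drops by ``m_drop_frac`` over
    ``m_drop_frames`` frames at M onset.  Per-pixel dispersion inside the
    nucleus ramps linearly to ``dispersion_peak`` at the programmed S/G2
    frame and narrows afterwards; late-S frames additionally carry
    ``n_speckles`` Gaussian puncta.  Images are 16-bit; the ROI is a static
    centred circle.

    Returns (movie uint16 [T, H, W], roi (cx, cy, r), SimTruth) where the
    truth holds per-frame labels and the S/G2 and M-onset change points.
    """
    if phase_schedule is None:
        phase_schedule = default_cycle_schedule()
    if any(n <= 0 for _, n in phase_schedule):
        raise ValueError("phase_schedule frame counts must be positive")
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    for phase, n in phase_schedule:
        if phase not in ("G1", "S", "lateS", "G2", "M"):
            raise ValueError(f"unknown phase {phase!r}")
        labels.extend([phase] * n)
    T = len(labels)

    # mean-intensity profile
    mean = np.empty(T)
    cur = base_intensity
    m_seen = 0
    for t, lab in enumerate(labels):
        if lab == "G1":
            cur *= np.exp(-g1_decay)
        elif lab in ("S", "lateS"):
            cur += s_slope * base_intensity
        elif lab == "G2":
            pass
        elif lab == "M":
            if m_seen < m_drop_frames:
                cur *= (1 - m_drop_frac) ** (1.0 / m_drop_frames)
                m_seen += 1
        mean[t] = cur

    # dispersion profile: ramp to peak at the S/G2 boundary, narrow after
    sg2_frame = None
    m_frame = None
    for t, lab in enumerate(labels):
        if lab == "G2" and sg2_frame is None:
            sg2_frame = t
        if lab == "M" and m_frame is None:
            m_frame = t
    sigma = np.full(T, dispersion_base)
    if sg2_frame is not None:
        # accelerating rise through S/lateS (replication heterogeneity grows
        # fastest near the transition), faster fall in G2
        for t in range(T):
            if t <= sg2_frame:
                frac = (t / max(sg2_frame, 1)) ** 2
            else:
                frac = max(0.0, 1.0 - (t - sg2_frame) / max(dispersion_fall_frames, 1))
            sigma[t] = dispersion_base + frac * (dispersion_peak - dispersion_base)
    if m_frame is not None:
        sigma[m_frame:] = dispersion_base

    cx = cy = img_size // 2
    yy, xx = np.mgrid[0:img_size, 0:img_size]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= roi_radius ** 2
    # chromatin texture: partially persistent between frames (AR(1) in time,
    # correlation rho) so bright spots drift rather than freeze in place
    rho = 0.5
    pattern0 = rng.standard_normal((img_size, img_size))

    # fixed speckle positions, pairwise separated, well inside the ROI
    speckle_pos = []
    tries = 0
    while len(speckle_pos) < n_speckles and tries < 2000:
        tries += 1
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, roi_radius - 5)
        px, py = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
        if all((px - qx) ** 2 + (py - qy) ** 2 >= 25 for qx, qy in speckle_pos):
            speckle_pos.append((px, py))
    speckle_field = np.zeros((img_size, img_size))
    for px, py in speckle_pos:
        speckle_field += np.exp(-((xx - px) ** 2 + (yy - py) ** 2) / (2 * 1.2 ** 2))

    # replication-focus envelope: foci brighten through late S, are maximal
    # at the S/G2 transition frame, and collapse over the first G2 frames
    env = np.zeros(T)
    late_idx = [t for t, lab in enumerate(labels) if lab == "lateS"]
    if late_idx:
        n_late = len(late_idx)
        for i, t in enumerate(late_idx):
            env[t] = 0.5 + 0.5 * (i + 1) / n_late
        if sg2_frame is not None:
            # replication foci disassemble gradually through early G2
            for off, frac in enumerate((1.0, 0.8, 0.6, 0.4, 0.2)):
                t = sg2_frame + off
                if t < T and labels[t] == "G2":
                    env[t] = frac

    frames = np.empty((T, img_size, img_size), dtype=np.uint16)
    bg = 0.05 * base_intensity
    for t in range(T):
        pattern = (rho * pattern0
                   + np.sqrt(1 - rho ** 2) * rng.standard_normal((img_size, img_size)))
        img = np.full((img_size, img_size), bg)
        img[mask] = mean[t] + pattern[mask] * sigma[t]
        if env[t] > 0:
            img += speckle_amp * env[t] * speckle_field
        img += rng.normal(0, noise_sd, (img_size, img_size))
        frames[t] = np.clip(img, 0, 65535).astype(np.uint16)

    truth = SimTruth(
        "movie", seed,
        {"phase_schedule": list(phase_schedule), "img_size": img_size,
         "roi_radius": roi_radius, "base_intensity": base_intensity,
         "g1_decay": g1_decay, "s_slope": s_slope,
         "n_speckles": len(speckle_pos), "speckle_amp": speckle_amp,
         "m_drop_frac": m_drop_frac, "m_drop_frames": m_drop_frames,
         "noise_sd": noise_sd, "dispersion_base": dispersion_base,
         "dispersion_peak": dispersion_peak,
         "dispersion_fall_frames": dispersion_fall_frames,
         "frame_interval_min": frame_interval_min},
        {"labels": labels, "t_sg2_frame": sg2_frame, "t_m_frame": m_frame,
         "mean_profile": mean.tolist(), "sigma_profile": sigma.tolist(),
         "speckle_envelope": env.tolist(),
         "speckle_positions": speckle_pos,
         "roi": (cx, cy, roi_radius)})
    return frames, (cx, cy, roi_radius), truth
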