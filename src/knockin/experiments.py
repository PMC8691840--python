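"""Replicated synthetic experiments at the study's scale.

These runners wire the simulators to the callers/classifiers and score the
results against the planted truth.  They are what the acceptance checks
execute: integration-site recovery on 100-kb heterozygous knock-in
libraries at 20x with 150-bp reads, copy-number discrimination between
single-copy heterozygotes and 3x tandem concatemers, and cell-cycle phase
recovery on synthetic nucleus movies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cellcycle as cc
from .mapper import map_pairs
from .simulate import (plant_insertion, simulate_locus, simulate_nucleus_movie,
                       simulate_read_pairs)
from .verification import (assess_copy_number, augment_reference,
                           call_integrations, cluster_anchors,
                           collect_anchor_pairs, collect_split_boundaries)

MOD31 = 2**31 - 1


def child_seed(seed: int, i: int, salt: int = 0) -> int:
    """Deterministic per-replicate sub-seed, kept below 2^31."""
    return (seed * 1_000_003 + 7919 * i + 104_729 * salt + 1) % MOD31


def run_integration_replicate(seed: int, host_len: int = 100_000,
                              insert_len: int = 714, depth: float = 20.0,
                              read_len: int = 150, error_rate: float = 0.001,
                              zygosity: str = "het", tandem_copies: int = 1,
                              with_insertion: bool = True,
                              insert_mean: float = 400.0,
                              insert_sd: float = 40.0, k: int = 31) -> dict:
    """One simulated WGS library pushed through the full caller.

    Returns truth and call summary for scoring: planted coordinate, the
    top call's coordinate/supports/depth ratio/copy class, and the number
    of calls and sub-threshold diagnostic clusters.
    """
    host = simulate_locus(host_len, gc=0.4, seed=child_seed(seed, 0, 1)).seq
    cassette = simulate_locus(insert_len, gc=0.45,
                              seed=child_seed(seed, 0, 2)).seq
    rng = np.random.default_rng(child_seed(seed, 0, 3))
    position = int(rng.integers(host_len // 5, 4 * host_len // 5))
    if with_insertion:
        alleles, _ = plant_insertion(host, cassette, position,
                                     zygosity=zygosity,
                                     tandem_copies=tandem_copies)
    else:
        alleles = {"wt": host}
    reads, _ = simulate_read_pairs(alleles, depth, read_len=read_len,
                                   insert_mean=insert_mean, insert_sd=insert_sd,
                                   error_rate=error_rate,
                                   seed=child_seed(seed, 0, 4))
    ref = augment_reference({"chr1": host}, {"tag": cassette})
    alns = map_pairs(reads, ref.contigs, k=k,
                     insert_mean=insert_mean, insert_sd=insert_sd)
    anchors = collect_anchor_pairs(alns, ref)
    clusters, low = cluster_anchors(anchors)
    splits = collect_split_boundaries(alns, ref)
    calls = [assess_copy_number(alns, c, ref)
             for c in call_integrations(clusters, splits)]
    top = calls[0] if calls else None
    return {
        "seed": seed,
        "true_coord": position if with_insertion else None,
        "n_calls": len(calls),
        "n_low_support": len(low),
        "called_coord": top.coordinate if top else None,
        "left_support": top.left_support if top else 0,
        "right_support": top.right_support if top else 0,
        "split_support": top.split_support if top else 0,
        "depth_ratio": top.depth_ratio if top else float("nan"),
        "copy_class": top.copy_class if top else None,
        "exact": bool(top and with_insertion and top.coordinate == position),
    }


def run_integration_experiment(n_runs: int, seed: int, **kw) -> pd.DataFrame:
    rows = [run_integration_replicate(child_seed(seed, i), **kw)
            for i in range(n_runs)]
    return pd.DataFrame(rows)


def run_cellcycle_replicate(seed: int, phase_schedule=None,
                            speckle_min: int = cc.DEFAULT_SPECKLE_MIN,
                            **movie_kw) -> dict:
    """One synthetic nucleus movie pushed through the phase classifier."""
    movie, (cx, cy, r), truth = simulate_nucleus_movie(
        phase_schedule=phase_schedule, seed=seed, **movie_kw)
    roi = cc.CircleROI(cx, cy, r)
    interval = truth.parameters["frame_interval_min"]
    trace = cc.normalize_trace(cc.extract_trace(movie, roi, interval))
    wtrace = cc.width_trace(movie, roi, frame_interval_min=interval)
    spk = cc.speckle_counts(movie, roi)
    seg = cc.segment_phases(trace, wtrace, spk, speckle_min=speckle_min,
                            frame_interval_min=interval)
    true_labels = truth.truth["labels"]
    acc = float(np.mean([a == b for a, b in zip(seg.labels, true_labels)]))
    t_sg2_true = truth.truth["t_sg2_frame"]
    t_m_true = truth.truth["t_m_frame"]
    return {
        "seed": seed,
        "accuracy": acc,
        "t_sg2_est": seg.t_sg2_frame, "t_sg2_true": t_sg2_true,
        "sg2_err": (abs(seg.t_sg2_frame - t_sg2_true)
                    if None not in (seg.t_sg2_frame, t_sg2_true) else None),
        "t_m_est": seg.t_m_frame, "t_m_true": t_m_true,
        "m_err": (abs(seg.t_m_frame - t_m_true)
                  if None not in (seg.t_m_frame, t_m_true) else None),
        "all_g1": all(l == "G1" for l in seg.labels),
    }


def run_cellcycle_experiment(n_runs: int, seed: int, **kw) -> pd.DataFrame:
    rows = [run_cellcycle_replicate(child_seed(seed, i, 11), **kw)
            for i in range(n_runs)]
    return pd.DataFrame(rows)
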