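"""File-format plumbing: FASTA/FASTQ, ROI tables, TIFF stacks, configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cellcycle import CircleROI


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq_pairs(pairs, path_r1, path_r2, quality_char: str = "F") -> None:
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for rp in pairs:
            f1.write(f"@{rp.name}/1\n{rp.seq1}\n+\n{quality_char * len(rp.seq1)}\n")
            f2.write(f"@{rp.name}/2\n{rp.seq2}\n+\n{quality_char * len(rp.seq2)}\n")


def read_fastq_pairs(path_r1, path_r2):
    """Paired reads as lightweight objects with name/seq1/seq2."""
    from .simulate import ReadPair
    r1 = list(SeqIO.parse(str(path_r1), "fastq"))
    r2 = list(SeqIO.parse(str(path_r2), "fastq"))
    if len(r1) != len(r2):
        raise ValueError("unequal mate counts in FASTQ pair")
    out = []
    for a, b in zip(r1, r2):
        name = a.id.rsplit("/", 1)[0]
        out.append(ReadPair(name, str(a.seq).upper(), str(b.seq).upper(),
                            allele="", frag_start=-1, frag_end=-1))
    return out


def write_movie(frames: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), frames)


def read_movie(path) -> np.ndarray:
    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        frames = frames[None]
    return frames


def write_roi_track(rois: list[CircleROI], path) -> None:
    with open(path, "w") as fh:
        fh.write("frame\tcx\tcy\tr\n")
        for f, r in enumerate(rois):
            fh.write(f"{f}\t{r.cx}\t{r.cy}\t{r.r}\n")


def read_roi_track(path) -> list[CircleROI]:
    rois = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            _, cx, cy, r = line.split("\t")
            rois.append(CircleROI(float(cx), float(cy), float(r)))
    return rois


def load_config(path) -> dict:
    """YAML (JSON accepted — it is a YAML subset)."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "__dict__"):
        return o.__dict__
    raise TypeError(f"not JSON serializable: {type(o)}")
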