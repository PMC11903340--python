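"""Readers and writers for the on-disk formats, and library-design geometry.

Tables travel as TSV so that any language can verify them; element catalogs
are BED6 (0-based, half-open; the strand column records the tested
orientation) plus FASTA with matching ids; motifs use the minimal MEME text
format. All genomic coordinates are 0-based half-open internally.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .grammar import PWM
from .synthetic import GroundTruth

__all__ = [
    "write_catalog",
    "read_catalog",
    "write_counts",
    "read_counts",
    "write_ground_truth",
    "read_ground_truth",
    "read_meme",
    "write_meme",
    "write_flat_config",
    "read_flat_config",
    "design_elements",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# element catalogs: BED6 + FASTA
# ---------------------------------------------------------------------------

def write_catalog(catalog: pd.DataFrame, bed_path, fasta_path) -> None:
    """Write a catalog as BED6 (score column carries the category) + FASTA."""
    bed = pd.DataFrame(
        {
            "chrom": catalog["chrom"],
            "start": catalog["start"].astype(int),
            "end": catalog["end"].astype(int),
            "name": catalog["element_id"],
            "score": 0,
            "strand": catalog["strand"],
        }
    )
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    records = [
        SeqRecord(
            Seq(row.sequence),
            id=row.element_id,
            description=f"category={row.category} cell_type={row.cell_type}",
        )
        for row in catalog.itertuples()
    ]
    SeqIO.write(records, fasta_path, "fasta")


def read_catalog(bed_path, fasta_path, expected_length: int | None = 200) -> pd.DataFrame:
    """Read a BED6 + FASTA catalog back into a catalog frame.

    BED names must match FASTA ids one-to-one; interval lengths must match
    the sequence lengths (and ``expected_length`` when given). Errors carry
    the offending BED line number.
    """
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    seqs: dict[str, str] = {}
    meta: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        meta[rec.id] = fields
    rows = []
    for i, row in enumerate(bed.itertuples(), start=1):
        if not isinstance(row.start, (int, np.integer)) or row.end <= row.start:
            raise ValueError(f"{bed_path}: malformed interval at line {i}")
        if row.name not in seqs:
            raise ValueError(f"{bed_path}: line {i}: id {row.name!r} missing from FASTA")
        seq = seqs[row.name]
        length = row.end - row.start
        if length != len(seq):
            raise ValueError(
                f"{bed_path}: line {i}: interval length {length} != sequence length {len(seq)}"
            )
        if expected_length is not None and length != expected_length:
            raise ValueError(
                f"{bed_path}: line {i}: length {length} != expected {expected_length}"
            )
        fields = meta[row.name]
        rows.append(
            (
                row.name,
                fields.get("category", ""),
                fields.get("cell_type", ""),
                row.chrom,
                int(row.start),
                int(row.end),
                row.strand,
                seq,
            )
        )
    extra = set(seqs) - set(bed["name"])
    if extra:
        raise ValueError(f"FASTA ids absent from BED: {sorted(extra)[:5]}")
    return pd.DataFrame(
        rows,
        columns=[
            "element_id",
            "category",
            "cell_type",
            "chrom",
            "start",
            "end",
            "strand",
            "sequence",
        ],
    )


# ---------------------------------------------------------------------------
# count / activity / truth tables: TSV
# ---------------------------------------------------------------------------

def write_counts(counts: pd.DataFrame, path) -> None:
    cols = ["element_id", "barcode", "replicate", "dna_count", "rna_count"]
    counts[cols].to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "element_id": str,
            "barcode": str,
            "replicate": int,
            "dna_count": int,
            "rna_count": int,
        },
    )
    missing = {"element_id", "barcode", "replicate", "dna_count", "rna_count"} - set(
        counts.columns
    )
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return counts


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Ground truth as one wide TSV: element metadata, site counts, activities."""
    wide = truth.elements.join(truth.site_counts.add_prefix("sites_")).join(
        truth.activity.add_prefix("activity_")
    )
    wide.to_csv(path, sep="\t")


def read_ground_truth(path) -> GroundTruth:
    wide = pd.read_csv(path, sep="\t", index_col="element_id")
    site_cols = [c for c in wide.columns if c.startswith("sites_")]
    act_cols = [c for c in wide.columns if c.startswith("activity_")]
    meta_cols = [c for c in wide.columns if c not in site_cols + act_cols]
    return GroundTruth(
        elements=wide[meta_cols],
        site_counts=wide[site_cols].rename(columns=lambda c: c[len("sites_") :]),
        activity=wide[act_cols].rename(columns=lambda c: c[len("activity_") :]),
    )


# ---------------------------------------------------------------------------
# motifs: minimal MEME format
# ---------------------------------------------------------------------------

def read_meme(path) -> list[PWM]:
    """Read PWMs from a minimal MEME motif file."""
    with open(path) as handle:
        parsed = motifs.parse(handle, "minimal")
    out = []
    for m in parsed:
        probs = np.column_stack([m.pwm[b] for b in "ACGT"])
        bg = np.array([m.background[b] for b in "ACGT"])
        out.append(PWM(m.name, probs, bg))
    return out


def write_meme(pwms: Sequence[PWM], path) -> None:
    """Write PWMs in minimal MEME format."""
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", ""]
    bg = pwms[0].background if pwms else np.full(4, 0.25)
    lines += [
        "Background letter frequencies",
        " ".join(f"{b} {f:.6f}" for b, f in zip("ACGT", bg)),
        "",
    ]
    for pwm in pwms:
        lines.append(f"MOTIF {pwm.name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= 20 E= 0"
        )
        for row in pwm.probs:
            lines.append(" ".join(f"{p:.6f}" for p in row))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# flat key-value configs
# ---------------------------------------------------------------------------

def write_flat_config(config: dict, path) -> None:
    lines = [f"{k} = {config[k]}" for k in sorted(config)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_flat_config(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {i}: expected 'key = value'")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


# ---------------------------------------------------------------------------
# library-design geometry
# ---------------------------------------------------------------------------

def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping intervals per chromosome (sorted sweep)."""
    merged = []
    for chrom, grp in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_s, cur_e = None, None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append((chrom, cur_s, cur_e))
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])


def _overlaps_any(chrom, start, end, other: pd.DataFrame) -> bool:
    sub = other[other["chrom"] == chrom]
    return bool(((sub["start"] < end) & (sub["end"] > start)).any())


def design_elements(
    peaks_rep1: pd.DataFrame,
    peaks_rep2: pd.DataFrame,
    tss: pd.DataFrame,
    flank: int = 100,
    promoter_pad: int = 2500,
) -> pd.DataFrame:
    """Design fixed-width candidate elements from replicated open-chromatin peaks.

    Peaks present in both replicates are merged; merged peaks within
    ``promoter_pad`` nt of any TSS are removed (promoter exclusion); each
    survivor is centered and extended +/-``flank`` nt to a 2*flank window.
    Inputs are BED-like frames with chrom/start/end (TSS uses its start as
    the site). All coordinates 0-based half-open.
    """
    for df, name in ((peaks_rep1, "peaks_rep1"), (peaks_rep2, "peaks_rep2"), (tss, "tss")):
        if not {"chrom", "start", "end"}.issubset(df.columns):
            raise ValueError(f"{name} needs chrom/start/end columns")
    m1 = _merge_intervals(peaks_rep1)
    m2 = _merge_intervals(peaks_rep2)
    keep = [
        row
        for row in m1.itertuples(index=False)
        if _overlaps_any(row.chrom, row.start, row.end, m2)
    ]
    keep += [
        row
        for row in m2.itertuples(index=False)
        if _overlaps_any(row.chrom, row.start, row.end, m1)
    ]
    if not keep:
        logger.warning("design_elements: no replicate-intersecting peaks")
        return pd.DataFrame(columns=["chrom", "start", "end"])
    merged = _merge_intervals(pd.DataFrame(keep, columns=["chrom", "start", "end"]))
    tss_pad = pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": (tss["start"] - promoter_pad).clip(lower=0),
            "end": tss["start"] + promoter_pad + 1,
        }
    )
    rows = []
    for row in merged.itertuples(index=False):
        if _overlaps_any(row.chrom, row.start, row.end, tss_pad):
            continue
        center = (row.start + row.end) // 2
        rows.append((row.chrom, max(0, center - flank), center + flank))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
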