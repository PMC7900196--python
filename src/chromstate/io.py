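"""Readers and writers for the pipeline's on-disk formats.

All interval formats are BED-dialect: 0-based, half-open, tab-separated.
Chromosome names are matched verbatim (no "chr" normalization). Binarized
observations use the ChromHMM text convention: per (biosample, chromosome)
file, a two-line header (biosample TAB chromosome, then mark names), then
one {0,1,2} row per bin with 2 meaning missing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .constants import MISSING, UNASSIGNED, UNASSIGNED_NAME
from .genome import BinnedGenome
from .hmm import HMMModel, ObservationSequence, Segmentation

_BED_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes",
    "blockStarts",
]


def read_bed(path: str | Path, genome: BinnedGenome | None = None) -> pd.DataFrame:
    """Read BED3/4/6/9/12 into a DataFrame; validates coordinates and, when
    a genome is given, rejects out-of-bounds records naming the line."""
    rows = []
    n_fields = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            if n_fields is None:
                n_fields = len(fields)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer start/end"
                ) from None
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            if genome is not None:
                if fields[0] not in genome.chrom_names:
                    raise ValueError(
                        f"{path}:{lineno}: unknown chromosome {fields[0]!r}"
                    )
                if end > genome.chrom_length(fields[0]):
                    raise ValueError(
                        f"{path}:{lineno}: interval exceeds chromosome bounds"
                    )
            rows.append([fields[0], start, end] + fields[3:])
    width = n_fields or 3
    return pd.DataFrame(rows, columns=_BED_COLUMNS[:width])


def write_bed(path: str | Path, intervals: pd.DataFrame) -> None:
    """Write the BED columns present in the DataFrame, in BED order."""
    cols = [c for c in _BED_COLUMNS if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def write_binarized(
    path: str | Path, seq: ObservationSequence
) -> None:
    """Write one (biosample, chromosome) observation matrix as ChromHMM
    binarized text; missing entries become 2."""
    vals = seq.values.copy()
    vals[vals == MISSING] = 2
    with open(path, "w") as fh:
        fh.write(f"{seq.biosample}\t{seq.chromosome}\n")
        fh.write("\t".join(seq.marks) + "\n")
        np.savetxt(fh, vals, fmt="%d", delimiter="\t")


def read_binarized(path: str | Path) -> ObservationSequence:
    """Inverse of :func:`write_binarized` (2 maps back to missing)."""
    with open(path) as fh:
        biosample, chromosome = fh.readline().rstrip("\n").split("\t")
        marks = fh.readline().rstrip("\n").split("\t")
        vals = np.loadtxt(fh, dtype=np.int8, delimiter="\t", ndmin=2)
    if vals.shape[1] != len(marks):
        raise ValueError(f"{path}: row width does not match the mark header")
    vals[vals == 2] = MISSING
    return ObservationSequence(biosample, chromosome, marks, vals)


def write_model(path: str | Path, model: HMMModel) -> None:
    """Flat TSV model serialization (header, emissions, transitions,
    initial); round-trips exactly via repr-precision floats."""
    with open(path, "w") as fh:
        fh.write(f"#states\t{model.n_states}\n")
        fh.write("#marks\t" + "\t".join(model.mark_names) + "\n")
        labels = model.state_labels or {}
        fh.write(
            "#labels\t"
            + "\t".join(labels.get(i, "") for i in range(model.n_states))
            + "\n"
        )
        for tag, block in (
            ("emissions", model.emissions),
            ("transitions", model.transitions),
            ("initial", model.initial[None, :]),
        ):
            for row in block:
                fh.write(tag + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_model(path: str | Path) -> HMMModel:
    emissions, transitions, initial = [], [], []
    marks: list[str] = []
    labels: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "#marks":
                marks = fields[1:]
            elif fields[0] == "#labels":
                labels = {i: v for i, v in enumerate(fields[1:]) if v}
            elif fields[0] == "emissions":
                emissions.append([float(v) for v in fields[1:]])
            elif fields[0] == "transitions":
                transitions.append([float(v) for v in fields[1:]])
            elif fields[0] == "initial":
                initial = [float(v) for v in fields[1:]]
    return HMMModel(
        marks, np.array(initial), np.array(transitions), np.array(emissions),
        state_labels=labels or None,
    )


_PALETTE = [
    "255,0,0", "255,69,0", "255,165,0", "255,215,0", "0,128,0", "0,100,0",
    "194,225,5", "255,255,0", "102,205,170", "138,145,208", "128,0,128",
    "189,183,107", "233,150,122", "128,128,128", "192,192,192", "169,169,169",
    "105,105,105", "0,0,128", "220,220,220", "47,79,79",
]


def write_segmentation_bed(path: str | Path, segmentation: Segmentation) -> None:
    """BED9 dense segmentation: one record per maximal same-state run."""
    genome = segmentation.genome
    w = genome.bin_size
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            labels = segmentation.labels[chrom]
            clen = genome.chrom_length(chrom)
            boundaries = np.flatnonzero(np.diff(labels) != 0) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(labels)]])
            for b0, b1 in zip(starts, ends):
                lab = int(labels[b0])
                name = segmentation.label_name(lab)
                rgb = "255,255,255" if lab == UNASSIGNED else _PALETTE[
                    lab % len(_PALETTE)
                ]
                s, e = b0 * w, min(b1 * w, clen)
                fh.write(
                    f"{chrom}\t{s}\t{e}\t{name}\t0\t.\t{s}\t{e}\t{rgb}\n"
                )


def read_segmentation_bed(
    path: str | Path, genome: BinnedGenome, state_names: list[str],
    biosample: str | None = None,
) -> Segmentation:
    """Rebuild a Segmentation from BED9 dense output (max posteriors are not
    stored in BED9 and come back as NaN)."""
    index = {name: k for k, name in enumerate(state_names)}
    index[UNASSIGNED_NAME] = UNASSIGNED
    labels = {
        c: np.full(genome.n_bins(c), UNASSIGNED, dtype=np.int16)
        for c in genome.chrom_names
    }
    df = read_bed(path, genome)
    w = genome.bin_size
    for _, r in df.iterrows():
        labels[r.chrom][int(r.start) // w: -(-int(r.end) // w)] = index[r["name"]]
    maxpost = {
        c: np.full(genome.n_bins(c), np.nan) for c in genome.chrom_names
    }
    return Segmentation(genome, state_names, labels, maxpost, biosample)


def write_bedgraph(
    path: str | Path, genome: BinnedGenome, values: dict[str, np.ndarray]
) -> None:
    """Per-bin values as bedGraph (one line per bin, NaN bins skipped)."""
    w = genome.bin_size
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            v = values[chrom]
            clen = genome.chrom_length(chrom)
            for i, val in enumerate(v):
                if np.isnan(val):
                    continue
                fh.write(f"{chrom}\t{i * w}\t{min((i + 1) * w, clen)}\t{val:g}\n")


def read_bedgraph(
    path: str | Path, genome: BinnedGenome, missing: float = np.nan
) -> dict[str, np.ndarray]:
    """Read bedGraph into per-bin vectors; positions without data get
    ``missing``. Values spanning several bins are assigned to each."""
    out = {
        c: np.full(genome.n_bins(c), missing, dtype=float)
        for c in genome.chrom_names
    }
    w = genome.bin_size
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")
            if chrom not in out:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            out[chrom][int(s) // w: -(-int(e) // w)] = float(v)
    return out


def write_expression(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
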