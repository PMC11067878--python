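"""Reading and writing annotation files.

Inputs are UCSC-style ``chrom.sizes`` tables, BED4+ segmentations
(``chrom  start  end  state[_mnemonic]``), and posterior matrices as
headerless TSV (G rows x K columns, global bin order) or an HDF5
container with a ``posterior`` dataset for large genomes.  Outputs are
bedGraph (r-values), BED (confident subset) and TSV summaries.  All
coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .annotation import MISSING, Annotation, AnnotationError
from .genome import BinnedGenome

if TYPE_CHECKING:  # pragma: no cover
    from .model import ConfidentAnnotation, RValueTrack

logger = logging.getLogger(__name__)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Parse a two-column chrom.sizes file into an ordered mapping."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def _parse_state_name(name: str) -> tuple[int, str | None]:
    """Split a BED name field into (state id, optional mnemonic).

    Accepts plain integers (``"3"``) or id-prefixed mnemonics (``"3_Enha"``).
    """
    head, _, tail = str(name).partition("_")
    try:
        sid = int(head)
    except ValueError:
        raise AnnotationError(f"cannot parse state id from BED name {name!r}") from None
    if sid < 0:
        raise AnnotationError(f"negative state id in BED name {name!r}")
    return sid, (tail or None)


def read_segmentation_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED4+ segmentation into a DataFrame with parsed state ids."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
        dtype={0: str, 1: np.int64, 2: np.int64, 3: str},
    )
    parsed = df["name"].map(_parse_state_name)
    df["state"] = [p[0] for p in parsed]
    df["mnemonic"] = [p[1] for p in parsed]
    return df


def read_posterior_matrix(path: str | Path) -> np.ndarray:
    """Read a G x K posterior matrix from headerless TSV or HDF5."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "r") as fh:
            return np.asarray(fh["posterior"], dtype=np.float64)
    return pd.read_csv(path, sep="\t", header=None, dtype=np.float64,
                       float_precision="round_trip").to_numpy()


def write_posterior_matrix(posterior: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("posterior", data=posterior)
    else:
        pd.DataFrame(posterior).to_csv(path, sep="\t", header=False, index=False,
                                       float_format="%.17g")


def read_annotation(
    segmentation_path: str | Path,
    genome: BinnedGenome,
    posterior_path: str | Path | None = None,
    K: int | None = None,
) -> Annotation:
    """Load a segmentation (plus optional posterior matrix) onto a binned genome.

    Each bin takes the state of the segment covering its midpoint; bins
    covered by no segment are flagged missing.  When a posterior matrix
    is supplied, labels are reconciled to the row argmax (see
    :class:`~sagarep.annotation.Annotation`).
    """
    seg = read_segmentation_bed(segmentation_path)
    labels = np.full(genome.G, MISSING, dtype=np.int64)
    mnemonics: dict[int, str] = {}
    for chrom, grp in seg.groupby("chrom", sort=False):
        if chrom not in genome.chrom_names:
            raise AnnotationError(f"BED chromosome {chrom!r} not in genome")
        ci = genome.chrom_index(chrom)
        size = genome.chrom_sizes[ci]
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (starts < 0).any() or (ends > size).any() or (ends <= starts).any():
            raise AnnotationError(f"invalid interval on {chrom}")
        if (starts[1:] < ends[:-1]).any():
            raise AnnotationError(f"overlapping segments on {chrom}")
        sl = genome.chrom_slices()[chrom]
        n = genome.n_bins_per_chrom[ci]
        bin_starts = np.arange(n, dtype=np.int64) * genome.resolution
        bin_ends = np.minimum(bin_starts + genome.resolution, size)
        mid = (bin_starts + bin_ends) // 2
        # segment covering each midpoint, or none
        idx = np.searchsorted(starts, mid, side="right") - 1
        states = grp["state"].to_numpy()
        covered = (idx >= 0) & (mid < ends[np.clip(idx, 0, None)])
        chrom_labels = np.full(n, MISSING, dtype=np.int64)
        chrom_labels[covered] = states[idx[covered]]
        labels[sl] = chrom_labels
        for sid, m in zip(states, grp["mnemonic"]):
            if m:
                mnemonics.setdefault(int(sid), m)

    posterior = None
    if posterior_path is not None:
        posterior = read_posterior_matrix(posterior_path)
        if posterior.shape[0] != genome.G:
            raise AnnotationError(
                f"posterior has {posterior.shape[0]} rows, expected G={genome.G}"
            )
        if labels.max() >= posterior.shape[1]:
            raise AnnotationError(
                f"BED state id {int(labels.max())} exceeds posterior column count "
                f"{posterior.shape[1]}"
            )
    if K is None:
        K = posterior.shape[1] if posterior is not None else int(labels.max()) + 1
    mnem = [mnemonics.get(k, str(k)) for k in range(K)]
    return Annotation(genome, labels, posterior, K=K, mnemonics=mnem)


# ----------------------------------------------------------------------
# writers

def _runs(values: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs [i, j) of equal values (NaN-safe; NaN != NaN treated equal)."""
    if len(values) == 0:
        return []
    v = np.asarray(values)
    if v.dtype.kind == "f":
        same = (v[1:] == v[:-1]) | (np.isnan(v[1:]) & np.isnan(v[:-1]))
    else:
        same = v[1:] == v[:-1]
    breaks = np.flatnonzero(~same) + 1
    edges = np.concatenate([[0], breaks, [len(v)]])
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def write_bedgraph(values: np.ndarray, genome: BinnedGenome, path: str | Path) -> None:
    """Write per-bin values as bedGraph, merging adjacent equal-valued bins.

    NaN bins are omitted.
    """
    with open(path, "w") as fh:
        for chrom, sl in genome.chrom_slices().items():
            vals = np.asarray(values[sl], dtype=np.float64)
            ci = genome.chrom_index(chrom)
            size = genome.chrom_sizes[ci]
            res = genome.resolution
            for a, b in _runs(vals):
                if np.isnan(vals[a]):
                    continue
                start = a * res
                end = min(b * res, size)
                fh.write(f"{chrom}\t{start}\t{end}\t{vals[a]:.17g}\n")


def read_bedgraph(path: str | Path, genome: BinnedGenome) -> np.ndarray:
    """Read a bedGraph back onto the bin grid; uncovered bins are NaN."""
    out = np.full(genome.G, np.nan)
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     float_precision="round_trip")
    res = genome.resolution
    slices = genome.chrom_slices()
    for row in df.itertuples(index=False):
        sl = slices[row.chrom]
        a = sl.start + int(row.start) // res
        b = sl.start + int(-(-row.end // res))
        out[a:b] = row.value
    return out


def write_confident_bed(
    labels: np.ndarray,
    mask: np.ndarray,
    genome: BinnedGenome,
    mnemonics: list[str],
    path: str | Path,
) -> None:
    """Write the confident subset as BED4: runs of confident, same-state bins."""
    with open(path, "w") as fh:
        for chrom, sl in genome.chrom_slices().items():
            lab = np.where(mask[sl], labels[sl], MISSING)
            ci = genome.chrom_index(chrom)
            size = genome.chrom_sizes[ci]
            res = genome.resolution
            for a, b in _runs(lab):
                sid = int(lab[a])
                if sid == MISSING:
                    continue
                start = a * res
                end = min(b * res, size)
                fh.write(f"{chrom}\t{start}\t{end}\t{sid}_{mnemonics[sid]}\n")


def write_tracks(
    rvalues: "RValueTrack",
    confident: "ConfidentAnnotation",
    out_prefix: str | Path,
) -> dict[str, Path]:
    """Write r-value bedGraph, confident-subset BED and per-state summary TSV.

    Returns a mapping of track kind to the file written.
    """
    if rvalues.genome is not confident.track.genome:
        raise AnnotationError("r-value track and confident annotation genome mismatch")
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "rvalues": prefix.with_name(prefix.name + ".rvalues.bedGraph"),
        "confident": prefix.with_name(prefix.name + ".confident.bed"),
        "summary": prefix.with_name(prefix.name + ".summary.tsv"),
    }
    genome = rvalues.genome
    write_bedgraph(rvalues.r, genome, paths["rvalues"])
    write_confident_bed(rvalues.state_of_record, confident.mask, genome,
                        rvalues.mnemonics, paths["confident"])
    rows = [("fraction_confident", "overall", confident.fraction_confident_overall)]
    for k, frac in enumerate(confident.fraction_confident_per_state):
        rows.append(("fraction_confident", str(k), frac))
    pd.DataFrame(rows, columns=["metric", "state", "value"]).to_csv(
        paths["summary"], sep="\t", index=False, float_format="%.17g"
    )
    return paths


def write_segmentation_bed(ann: Annotation, path: str | Path) -> None:
    """Write an annotation's MAP labels as a BED4 segmentation (missing bins skipped)."""
    write_confident_bed(ann.labels, ann.labels >= 0, ann.genome, ann.mnemonics, path)
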