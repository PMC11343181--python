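"""Colocalization of significance maps and cohort report assembly.

Two signed significance maps in the same atlas space (e.g. plaque count
change vs microglia volume change) are compared by counting the voxels where
the significantly increasing or decreasing parts of one map overlap the
significantly increasing or decreasing parts of the other -- four
comparisons, summarized as a 2x2 colocalization matrix.  Raw voxel counts
are the primary output; proportions normalized by each map's category totals
are emitted alongside since figure scalings vary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas_space import AtlasGrid, LabelAtlas, group_regional_stats, regional_table
from .voxel_stats import SignificanceMap

_CATEGORIES = ("increase", "decrease")
_SIGNS = {"increase": 1, "decrease": -1}


@dataclass
class ColocalizationMatrix:
    """2x2 voxel-overlap table; rows index map 1, columns map 2."""

    counts: np.ndarray  # (2, 2) int, order: increase, decrease
    map1_totals: dict[str, int]
    map2_totals: dict[str, int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64).reshape(2, 2)
        if np.any(self.counts < 0):
            raise ValueError("overlap counts cannot be negative")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, cat1 in enumerate(_CATEGORIES):
            for j, cat2 in enumerate(_CATEGORIES):
                n = int(self.counts[i, j])
                t1 = self.map1_totals[cat1]
                t2 = self.map2_totals[cat2]
                rows.append(
                    {
                        "map1_category": cat1,
                        "map2_category": cat2,
                        "overlap_voxels": n,
                        "map1_total": t1,
                        "map2_total": t2,
                        "fraction_of_map1": n / t1 if t1 else 0.0,
                        "fraction_of_map2": n / t2 if t2 else 0.0,
                    }
                )
        return pd.DataFrame(rows)


def colocalization_matrix(map1: SignificanceMap, map2: SignificanceMap) -> ColocalizationMatrix:
    """Count overlapping voxels between the signed categories of two maps."""
    v1, v2 = map1.values, map2.values
    if v1.shape != v2.shape:
        raise ValueError(f"shape mismatch: {v1.shape} vs {v2.shape}")
    counts = np.zeros((2, 2), dtype=np.int64)
    for i, cat1 in enumerate(_CATEGORIES):
        for j, cat2 in enumerate(_CATEGORIES):
            counts[i, j] = int(np.count_nonzero((v1 == _SIGNS[cat1]) & (v2 == _SIGNS[cat2])))
    totals1 = {c: int(np.count_nonzero(v1 == _SIGNS[c])) for c in _CATEGORIES}
    totals2 = {c: int(np.count_nonzero(v2 == _SIGNS[c])) for c in _CATEGORIES}
    return ColocalizationMatrix(counts, totals1, totals2)


@dataclass
class ReportBundle:
    """Tabular cohort report: regional group statistics, significant-voxel
    fractions per region, and (optionally) the colocalization matrix."""

    regional_group_stats: pd.DataFrame
    significant_fractions: pd.DataFrame
    colocalization: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        tables = {
            "regional_group_stats.csv": self.regional_group_stats,
            "significant_fractions.csv": self.significant_fractions,
        }
        if self.colocalization is not None:
            tables["colocalization.csv"] = self.colocalization
        header = "".join(f"# {k}: {v}\n" for k, v in sorted(self.provenance.items()))
        for name, table in tables.items():
            path = outdir / name
            with open(path, "w") as fh:
                fh.write(header)
                table.to_csv(fh, index=False)
            written.append(path)
        return written


def significant_fractions(sig: SignificanceMap, atlas: LabelAtlas) -> pd.DataFrame:
    """Per region: voxel counts and fractions labeled decrease / increase."""
    if sig.values.shape != atlas.shape:
        raise ValueError("significance map does not match atlas shape")
    rows = []
    for rid in (int(i) for i in atlas.regions["id"]):
        region = atlas.labels == rid
        n = int(region.sum())
        dec = int(np.count_nonzero(region & (sig.values == -1)))
        inc = int(np.count_nonzero(region & (sig.values == 1)))
        rows.append(
            {
                "region_id": rid,
                "name": atlas.region_name(rid),
                "n_voxels": n,
                "n_decrease": dec,
                "n_increase": inc,
                "frac_decrease": dec / n if n else 0.0,
                "frac_increase": inc / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def cohort_report(
    atlas: LabelAtlas,
    sample_grids: list[AtlasGrid],
    sample_groups: list[str],
    sig: SignificanceMap,
    coloc: ColocalizationMatrix | None = None,
    provenance: dict | None = None,
) -> ReportBundle:
    """Assemble the tabular cohort report.

    Inputs must share one atlas; shape mismatches are rejected.  The regional
    group statistics aggregate each sample's quantity grid over regions and
    reduce to per-group mean/SD; the significance map yields per-region
    significant-voxel fractions.
    """
    if len(sample_grids) != len(sample_groups):
        raise ValueError("one group label per sample grid required")
    for grid in sample_grids:
        if grid.shape != atlas.shape:
            raise ValueError("sample grid does not match atlas shape")
    tables = [regional_table(grid, atlas) for grid in sample_grids]
    stats = group_regional_stats(tables, sample_groups)
    fractions = significant_fractions(sig, atlas)
    return ReportBundle(
        regional_group_stats=stats,
        significant_fractions=fractions,
        colocalization=coloc.to_dataframe() if coloc is not None else None,
        provenance=dict(provenance or {}),
    )


def render_overlay(
    sig: SignificanceMap,
    atlas: LabelAtlas,
    path: str | Path,
    axis: int = 0,
    n_slices: int = 4,
) -> Path:
    """Visual QC: coronal-style slices of the ternary map over the atlas.

    Decrease voxels render red, increase cyan, atlas anatomy grey.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if sig.values.shape != atlas.shape:
        raise ValueError("significance map does not match atlas shape")
    size = atlas.shape[axis]
    picks = np.linspace(size * 0.2, size * 0.8, n_slices).astype(int)
    fig, axes = plt.subplots(1, n_slices, figsize=(3 * n_slices, 3))
    ternary_cmap = ListedColormap([(1, 0.2, 0.2), (0, 0, 0, 0), (0.2, 0.9, 0.9)])
    for ax, k in zip(np.atleast_1d(axes), picks):
        anatomy = np.take(atlas.labels > 0, k, axis=axis)
        ternary = np.take(sig.values, k, axis=axis)
        ax.imshow(anatomy.T, cmap="gray", vmin=0, vmax=2, origin="lower")
        ax.imshow(
            np.ma.masked_equal(ternary, 0).T,
            cmap=ternary_cmap, vmin=-1, vmax=1, origin="lower", alpha=0.9,
        )
        ax.set_title(f"slice {k}")
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)


__all__ = [
    "ColocalizationMatrix",
    "ReportBundle",
    "colocalization_matrix",
    "significant_fractions",
    "cohort_report",
    "render_overlay",
]
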