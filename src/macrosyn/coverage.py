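"""X chromosome identification from male vs asexual-female read depth.

In X0 sex determination, males carry one X and females two, so male read
depth on the X is half the female depth while autosomes match. The caller
works on fixed windows (100 kb by default): the raw male:female ratio is
normalized by a coverage correction factor (mean male depth over mean
female depth on putative autosomes, the equivalent of multiplying the
female depth so autosomal ratios center on 1), then chromosomes are called
X when most windows sit near ratio 0.5 and autosome when they sit near 1.

The calling thresholds are not biology, just separation of Poisson
sampling noise at >= 20x depth, and are all configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["window_depth_ratio", "normalization_factor", "call_x"]


def window_depth_ratio(
    depth_m: pd.DataFrame, depth_f: pd.DataFrame, window: int = 100_000
) -> pd.DataFrame:
    """Combine male and female per-window depth tables into coverage windows.

    Input tables carry chrom/start/end/depth rows (any window size that
    nests into ``window``); depths are averaged per output window. Windows
    with zero female depth are flagged ``excluded`` and trailing partial
    windows shorter than half the window size are dropped.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    chroms_m = set(depth_m["chrom"])
    chroms_f = set(depth_f["chrom"])
    if chroms_m != chroms_f:
        raise ValueError(
            f"mismatched chromosome sets: {sorted(chroms_m ^ chroms_f)}"
        )

    def rewindow(df: pd.DataFrame, col: str) -> pd.DataFrame:
        d = df.copy()
        mid = (d["start"] + d["end"]) / 2.0
        d["wstart"] = (mid // window).astype(int) * window
        g = d.groupby(["chrom", "wstart"], as_index=False).agg(
            depth=("depth", "mean"), end=("end", "max")
        )
        return g.rename(columns={"depth": col})

    m = rewindow(depth_m, "depth_m")
    f = rewindow(depth_f, "depth_f")
    out = m.merge(f[["chrom", "wstart", "depth_f"]], on=["chrom", "wstart"])
    out = out.rename(columns={"wstart": "start"})
    out = out[(out["end"] - out["start"]) >= window / 2].reset_index(drop=True)
    out["ratio_raw"] = np.where(
        out["depth_f"] > 0, out["depth_m"] / out["depth_f"], np.nan
    )
    out["excluded"] = out["depth_f"] == 0
    return out[["chrom", "start", "end", "depth_m", "depth_f", "ratio_raw", "excluded"]]


def normalization_factor(windows: pd.DataFrame, excluded_chroms=()) -> float:
    """Coverage correction factor: mean male depth over mean female depth
    across windows outside ``excluded_chroms`` (the putative X).

    The factor is applied unrounded (report it rounded to 1 decimal); the
    female depth is scaled up by it, i.e. normalized ratio = raw / factor.
    """
    keep = windows[~windows["chrom"].isin(set(excluded_chroms)) & ~windows["excluded"]]
    if len(keep) == 0:
        raise ValueError("no windows left outside excluded chromosomes")
    mean_f = float(keep["depth_f"].mean())
    if mean_f == 0:
        raise ValueError("zero female mean depth")
    return float(keep["depth_m"].mean()) / mean_f


def call_x(
    windows: pd.DataFrame,
    screen_ratio: float = 0.75,
    x_band: tuple[float, float] = (0.35, 0.65),
    autosome_band: tuple[float, float] = (0.8, 1.2),
    band_fraction: float = 0.8,
    min_windows: int = 20,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Two-pass X calling from coverage windows.

    Pass 1 screens candidate X chromosomes (median raw ratio below
    ``screen_ratio`` x the genome-wide median); pass 2 recomputes the
    correction factor excluding candidates and classifies each chromosome:
    X if >= ``band_fraction`` of its normalized ratios fall in ``x_band``,
    autosome if that fraction falls in ``autosome_band``, else ambiguous.
    Chromosomes with fewer than ``min_windows`` usable windows are
    ambiguous. Returns (calls, windows with ratio_norm).
    """
    usable = windows[~windows["excluded"]]
    if len(usable) == 0:
        raise ValueError("no usable coverage windows")
    genome_median = float(usable["ratio_raw"].median())
    medians = usable.groupby("chrom")["ratio_raw"].median()
    candidates = set(medians[medians < screen_ratio * genome_median].index)

    factor = normalization_factor(windows, excluded_chroms=candidates)
    out = windows.copy()
    out["ratio_norm"] = out["ratio_raw"] / factor

    calls: dict[str, str] = {}
    for chrom, grp in out[~out["excluded"]].groupby("chrom"):
        if len(grp) < min_windows:
            calls[chrom] = "ambiguous"
            continue
        r = grp["ratio_norm"]
        frac_x = float(((r >= x_band[0]) & (r <= x_band[1])).mean())
        frac_a = float(((r >= autosome_band[0]) & (r <= autosome_band[1])).mean())
        if frac_x >= band_fraction:
            calls[chrom] = "X"
        elif frac_a >= band_fraction:
            calls[chrom] = "autosome"
        else:
            calls[chrom] = "ambiguous"
    for chrom in set(windows["chrom"]) - set(calls):
        calls[chrom] = "ambiguous"
    return calls, out
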