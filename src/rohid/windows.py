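"""Regional ROH-burden scan in non-overlapping genomic windows.

The genome is tiled with 3-Mb windows; per window, trait residuals are
regressed on the fraction of the window covered by each sample's ROH, with
Bonferroni control over the tested windows and QQ output for calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

WINDOW_WIDTH_BP = 3_000_000
MIN_REMAINDER_BP = 1_000_000


@dataclass(frozen=True)
class GenomicWindow:
    """One tiling window, 1-based inclusive."""

    chrom: str
    start_bp: int
    end_bp: int
    index: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def make_windows(
    chromosome_lengths,
    width: int = WINDOW_WIDTH_BP,
    min_remainder: int = MIN_REMAINDER_BP,
) -> list[GenomicWindow]:
    """Tile each chromosome with consecutive ``width``-bp windows.

    A terminal remainder shorter than ``min_remainder`` is merged into the
    previous window (kept as its own window otherwise, or when it is the
    only window on the chromosome).
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    windows: list[GenomicWindow] = []
    for ci, length in enumerate(chromosome_lengths, start=1):
        length = int(length)
        if length <= 0:
            raise ValueError("chromosome lengths must be positive")
        chrom = str(ci)
        bounds = []
        start = 1
        while start <= length:
            end = min(start + width - 1, length)
            bounds.append((start, end))
            start = end + 1
        if len(bounds) > 1 and (bounds[-1][1] - bounds[-1][0] + 1) < min_remainder:
            last = bounds.pop()
            prev = bounds.pop()
            bounds.append((prev[0], last[1]))
        for s, e in bounds:
            windows.append(GenomicWindow(chrom, s, e, len(windows)))
    return windows


def window_roh_fraction(segments, windows, sample_ids) -> pd.DataFrame:
    """Samples-by-windows matrix of the window fraction covered by ROH.

    ``segments`` is either a list of :class:`~rohid.core.ROHSegment` or a
    frame with columns ``sample_id, chrom, start_bp, end_bp`` (1-based
    inclusive). Entries lie in [0, 1].
    """
    if isinstance(segments, pd.DataFrame):
        seg_iter = segments[["sample_id", "chrom", "start_bp", "end_bp"]].itertuples(index=False)
    else:
        seg_iter = ((s.sample_id, s.chrom, s.start_bp, s.end_bp) for s in segments)

    sample_ids = list(sample_ids)
    row_of = {sid: i for i, sid in enumerate(sample_ids)}
    frac = np.zeros((len(sample_ids), len(windows)))

    by_chrom: dict[str, list[GenomicWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    starts = {c: np.array([w.start_bp for w in ws]) for c, ws in by_chrom.items()}

    for sample_id, chrom, seg_start, seg_end in seg_iter:
        if sample_id not in row_of or str(chrom) not in by_chrom:
            continue
        ws = by_chrom[str(chrom)]
        st = starts[str(chrom)]
        lo = max(0, int(np.searchsorted(st, seg_start, side="right")) - 1)
        row = row_of[sample_id]
        for w in ws[lo:]:
            if w.start_bp > seg_end:
                break
            overlap = min(w.end_bp, seg_end) - max(w.start_bp, seg_start) + 1
            if overlap > 0:
                frac[row, w.index] += overlap / w.length_bp
    np.clip(frac, 0.0, 1.0, out=frac)
    return pd.DataFrame(frac, index=sample_ids, columns=[w.index for w in windows])


def scan(
    residuals,
    fraction_matrix: pd.DataFrame,
    windows=None,
    alpha: float = 0.05,
    min_informative: int = 25,
    fixed_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-window simple linear regression of residuals on ROH fraction.

    Windows with fewer than ``min_informative`` samples of nonzero
    fraction, or a zero-variance fraction column, are flagged untested.
    The Bonferroni threshold is ``alpha / n_tested`` unless a
    ``fixed_threshold`` is supplied.
    """
    y = np.asarray(residuals, dtype=float)
    x = fraction_matrix.to_numpy(float)
    n, m = x.shape
    if len(y) != n:
        raise ValueError("residuals and fraction matrix are not aligned")

    n_informative = (x > 0).sum(axis=0)
    yc = y - y.mean()
    syy = float(yc @ yc)
    xc = x - x.mean(axis=0)
    sxx = (xc * xc).sum(axis=0)
    sxy = xc.T @ yc

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pvals = np.full(m, np.nan)
    tested = (n_informative >= min_informative) & (sxx > 0) & (n > 2)

    ok = tested & (sxx > 0)
    beta[ok] = sxy[ok] / sxx[ok]
    sse = np.maximum(syy - beta * sxy, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = sse / max(n - 2, 1)
        se[ok] = np.sqrt(sigma2[ok] / sxx[ok])
        tstat = np.where(se > 0, beta / se, np.nan)
    df = max(n - 2, 1)
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df)
    # a zero-variance response leaves beta = 0 with an undefined p: degenerate
    tested = tested & np.isfinite(pvals)

    n_tested = int(tested.sum())
    threshold = fixed_threshold if fixed_threshold is not None else (
        alpha / n_tested if n_tested else np.nan
    )
    out = pd.DataFrame(
        {
            "window": fraction_matrix.columns,
            "beta": beta,
            "se": se,
            "p": pvals,
            "n_informative": n_informative,
            "tested": tested,
        }
    )
    out["significant"] = tested & (out["p"] < threshold)
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["n_tested"] = n_tested
    if windows is not None:
        meta = pd.DataFrame(
            {
                "window": [w.index for w in windows],
                "chrom": [w.chrom for w in windows],
                "start_bp": [w.start_bp for w in windows],
                "end_bp": [w.end_bp for w in windows],
            }
        )
        out = meta.merge(out, on="window")
        out.attrs["bonferroni_threshold"] = threshold
        out.attrs["n_tested"] = n_tested
    return out


def qq_points(p_values) -> pd.DataFrame:
    """Expected vs observed -log10(p) pairs for a QQ plot.

    Expected quantiles are ``-log10((i - 0.5) / m)`` against the sorted
    observed values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    p_sorted = np.sort(p)
    m = len(p_sorted)
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(p_sorted)
    return pd.DataFrame({"expected": expected, "observed": observed})
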