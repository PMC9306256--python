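"""Human/mouse DNA mixture deconvolution for patient-derived xenografts.

Two estimators of the human DNA fraction of a mixed sample:

1. *Variant-probe method* — a small set of human-mouse syntenic Infinium-I
   probes carry a single-nucleotide difference at the extension base, so
   the human template fluoresces in one color channel and the mouse
   template in the other. The per-probe ratio Human/(Human+Mouse) of
   channel totals is summarized by its median.
2. *Intensity method* — the same DNA run on both a mouse and a human
   array; the ratio of median total intensities over each array's
   non-syntenic probes, Human/(Human+Mouse).

Both raw ratios are calibrated against titration standard curves (known
human fractions vs. observed ratios) fitted with LOESS and averaged
across calibration tissues, then inverted by isotonic projection +
linear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.smoothers_lowess import lowess

from .manifest import Manifest
from .preprocess import SignalFrame

#: Human-fraction titration points used for standard curves.
TITRATION_FRACTIONS = (0.0, 0.05, 0.1, 0.15, 0.25, 0.5, 0.75, 0.85, 0.9, 0.95, 1.0)


class MixtureError(ValueError):
    pass


@dataclass
class TitrationSeries:
    """Known human proportions vs. observed Human/(Human+Mouse) ratios for
    one calibration sample source (e.g. a tissue)."""

    fractions: np.ndarray
    ratios: np.ndarray
    calibration_label: str = ""

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if len(self.fractions) != len(self.ratios):
            raise MixtureError("fractions and ratios must have equal length")
        if not np.all(np.diff(self.fractions) > 0):
            raise MixtureError("titration fractions must be strictly increasing")


@dataclass
class StandardCurve:
    """Fitted ratio as a function of the true human fraction on a fine
    grid, with an isotonic projection for unique inversion."""

    grid: np.ndarray
    fitted: np.ndarray
    loess_span: float
    monotone: np.ndarray = field(init=False)
    invertible: bool = field(init=False)

    def __post_init__(self) -> None:
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        self.monotone = iso.fit_transform(self.grid, self.fitted)
        self.invertible = bool(self.monotone[-1] > self.monotone[0])

    def __call__(self, fraction) -> np.ndarray:
        return np.interp(fraction, self.grid, self.fitted)

    def invert(self, ratio: float) -> float:
        """Human fraction whose fitted ratio equals ``ratio``, clamped to
        [0, 1] (with a warning) outside the fitted range."""
        if not self.invertible:
            raise MixtureError("standard curve is constant; cannot invert")
        lo, hi = self.monotone[0], self.monotone[-1]
        if ratio < lo or ratio > hi:
            warnings.warn(
                f"ratio {ratio:.4g} outside fitted range [{lo:.4g}, {hi:.4g}]; clamped"
            )
            return float(self.grid[0] if ratio < lo else self.grid[-1])
        # strictly increasing support for a unique interpolated inverse
        keep = np.concatenate(([True], np.diff(self.monotone) > 0))
        return float(np.interp(ratio, self.monotone[keep], self.grid[keep]))


def variant_probe_ratio(
    signals: SignalFrame, manifest: Manifest
) -> tuple[pd.Series, float]:
    """Per-probe and summary Human/(Human+Mouse) channel-total ratios from
    channel-switch (human-mouse variant) probes.

    The manifest flags these probes with category ``channel_switch`` and
    records in ``snp_alt_channel_species`` which species' template reads
    in the channel *opposite* the probe's design channel. The summary is
    the median across probes; probes with zero total in both channels are
    skipped with a warning.
    """
    man = manifest.df
    flagged = manifest.has_category("channel_switch")
    ids = man.index[flagged].intersection(signals.df.index)
    if len(ids) == 0:
        raise MixtureError("manifest flags no channel_switch probes")
    df = signals.df.loc[ids]
    sub = man.loc[ids]
    green_total = df["MG"] + df["UG"]
    red_total = df["MR"] + df["UR"]
    # design channel holds one species, the opposite channel the other
    alt_is_human = sub["snp_alt_channel_species"] == "Human"
    design_green = sub["channel"] == "Green"
    human_in_green = (design_green & ~alt_is_human) | (~design_green & alt_is_human)
    human = green_total.where(human_in_green, red_total)
    mouse = red_total.where(human_in_green, green_total)
    total = human + mouse
    zero = total <= 0
    if zero.any():
        warnings.warn(f"skipping {int(zero.sum())} variant probes with zero total signal")
    ratios = (human / total)[~zero].rename("human_ratio")
    if len(ratios) == 0:
        raise MixtureError("no variant probe with nonzero signal")
    return ratios, float(ratios.median())


def intensity_ratio(
    human_array_signals: SignalFrame,
    mouse_array_signals: SignalFrame,
    human_manifest: Manifest,
    mouse_manifest: Manifest,
    nonsyntenic_category: str = "nonsyntenic",
) -> float:
    """Median-intensity ratio Human/(Human+Mouse) from one sample run on
    both array types, using each array's species-specific (non-syntenic)
    probes."""

    def _median_total(signals: SignalFrame, manifest: Manifest) -> float:
        ids = manifest.df.index[manifest.has_category(nonsyntenic_category)]
        ids = ids.intersection(signals.df.index)
        if len(ids) == 0:
            raise MixtureError(
                f"no {nonsyntenic_category!r} probes shared between signals and manifest"
            )
        df = signals.df.loc[ids]
        return float((df["MG"] + df["UG"] + df["MR"] + df["UR"]).median())

    med_h = _median_total(human_array_signals, human_manifest)
    med_m = _median_total(mouse_array_signals, mouse_manifest)
    if med_h + med_m <= 0:
        raise MixtureError("zero total intensity on both arrays")
    return med_h / (med_h + med_m)


def fit_standard_curve(
    series: list[TitrationSeries],
    span: float = 0.75,
    grid_step: float = 0.005,
    min_points: int = 5,
) -> StandardCurve:
    """Fit a standard curve from one or more titration series.

    Each series gets a degree-1 tricube-weighted LOESS fit of ratio on
    fraction evaluated on a [0, 1] grid; the curve is the pointwise mean
    across series (the calibration design uses two tissue sources)."""
    if not series:
        raise MixtureError("need at least one titration series")
    for s in series:
        if len(s.fractions) < min_points:
            raise MixtureError(
                f"titration series {s.calibration_label!r} has {len(s.fractions)} "
                f"points; need >= {min_points}"
            )
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    fits = []
    for s in series:
        fit = lowess(s.ratios, s.fractions, frac=span, it=0, xvals=grid)
        fits.append(fit)
    fitted = np.mean(fits, axis=0)
    curve = StandardCurve(grid=grid, fitted=fitted, loess_span=span)
    if not curve.invertible:
        warnings.warn("fitted standard curve is non-increasing everywhere; inversion will fail")
    return curve


def estimate_fraction(ratio: float, curve: StandardCurve) -> float:
    """Invert a standard curve at an observed ratio -> human fraction."""
    return curve.invert(ratio)


class HumanFractionEstimator:
    """Calibrated human-fraction estimator (sklearn-style).

    ``fit`` takes a titration table (columns calibration_label, fraction,
    ratio) and learns the standard curve; ``predict`` maps observed
    ratios to human fractions. With ``calibrated=False`` predict returns
    the raw ratios (calibration-free use).

    Parameters
    ----------
    span : float, default 0.75
        LOESS span for the standard curve.
    calibrated : bool, default True
    """

    def __init__(self, span: float = 0.75, calibrated: bool = True):
        self.span = span
        self.calibrated = calibrated

    def get_params(self, deep: bool = True) -> dict:
        return {"span": self.span, "calibrated": self.calibrated}

    def set_params(self, **params) -> "HumanFractionEstimator":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, titrations: pd.DataFrame, y=None) -> "HumanFractionEstimator":
        series = [
            TitrationSeries(
                fractions=g.sort_values("fraction")["fraction"].to_numpy(),
                ratios=g.sort_values("fraction")["ratio"].to_numpy(),
                calibration_label=str(label),
            )
            for label, g in titrations.groupby("calibration_label")
        ]
        self.curve_ = fit_standard_curve(series, span=self.span)
        return self

    def predict(self, ratios) -> np.ndarray:
        ratios = np.atleast_1d(np.asarray(ratios, dtype=float))
        if not self.calibrated:
            return np.clip(ratios, 0.0, 1.0)
        if not hasattr(self, "curve_"):
            raise MixtureError("estimator is not fitted; call fit() first")
        return np.array([self.curve_.invert(r) for r in ratios])


def load_titrations(path) -> pd.DataFrame:
    """Read a titration CSV (calibration_label, fraction, ratio)."""
    df = pd.read_csv(path)
    needed = {"calibration_label", "fraction", "ratio"}
    if not needed.issubset(df.columns):
        raise MixtureError(f"titration table must have columns {sorted(needed)}")
    return df
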