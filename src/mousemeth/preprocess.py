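"""Raw two-channel signal preprocessing to masked β values.

Infinium-I probes read both alleles in a single design channel, leaving
their opposite-channel fluorescence ("out-of-band", OOB) as a pure
background proxy. The pipeline follows the standard order: empirical
detection p-values against the OOB distribution (pOOBAH), then
normal-exponential background subtraction using the OOB moments (noob),
then a nonlinear dye-bias correction equalizing the Red and Green Type-I
intensity distributions, and finally β = M/(M+U) with masking of
undetected and default-masked probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .manifest import Manifest

SIGNAL_COLUMNS = ["MG", "UG", "MR", "UR"]


class PreprocessError(ValueError):
    pass


class SignalFrame:
    """Per-sample allele-level intensities in both color channels.

    One row per probe, columns MG/UG/MR/UR = methylated / unmethylated
    allele intensity in Green / Red (arbitrary fluorescence units >= 0).
    For Infinium-I probes the design channel holds the in-band signals and
    the other channel the out-of-band ones; Infinium-II probes read the
    methylated allele in Green and the unmethylated in Red.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if "probe_id" in df.columns:
            df = df.set_index("probe_id")
        missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
        if missing:
            raise PreprocessError(f"signal frame missing columns {missing}")
        df = df[SIGNAL_COLUMNS].astype(float)
        if (df.to_numpy() < 0).any():
            raise PreprocessError("signal intensities must be >= 0")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_tsv(cls, path) -> "SignalFrame":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.df.reset_index(names="probe_id").to_csv(path, sep="\t", index=False)

    def copy(self) -> "SignalFrame":
        return SignalFrame(self.df.copy())


@dataclass
class OOBSet:
    """Out-of-band intensity vectors per channel.

    oob_green collects Green fluorescence of Red-channel Infinium-I probes
    (both alleles); oob_red the converse.
    """

    oob_green: np.ndarray
    oob_red: np.ndarray

    def channel(self, ch: str) -> np.ndarray:
        return self.oob_green if ch == "Green" else self.oob_red


@dataclass
class NormexpParams:
    """Normal-exponential convolution parameters for one channel:
    background ~ N(mu_b, sigma_b^2), signal ~ Exponential(alpha)."""

    mu_b: float
    sigma_b: float
    alpha: float


def extract_oob(signals: SignalFrame, manifest: Manifest) -> OOBSet:
    """Collect out-of-band intensities from Infinium-I probes.

    Green OOB comes from Red-channel Type-I probes (their MG and UG);
    Red OOB from Green-channel Type-I probes (MR and UR). Channel-switch
    (species-variant) probes are excluded: they legitimately fluoresce in
    either channel depending on the template species, so their
    opposite-channel signal is not background.
    """
    switch = manifest.df.index[manifest.has_category("channel_switch")]
    red_i = manifest.type_i_ids("Red").difference(switch).intersection(signals.df.index)
    grn_i = manifest.type_i_ids("Green").difference(switch).intersection(signals.df.index)
    if len(red_i) == 0 and len(grn_i) == 0:
        raise PreprocessError(
            "manifest has no Infinium-I probes; background cannot be estimated"
        )
    oob_green = signals.df.loc[red_i, ["MG", "UG"]].to_numpy().ravel()
    oob_red = signals.df.loc[grn_i, ["MR", "UR"]].to_numpy().ravel()
    return OOBSet(oob_green=oob_green, oob_red=oob_red)


def _inband_totals(signals: SignalFrame, manifest: Manifest) -> pd.DataFrame:
    """Per-probe in-band total intensity and its channel ('Green'/'Red'/'Both').

    Infinium-I: M+U in the design channel. Infinium-II: totals in both
    channels are reported separately (MG+UG green, MR+UR red).
    """
    df = signals.df
    man = manifest.df.loc[df.index]
    out = pd.DataFrame(index=df.index, columns=["green_total", "red_total"], dtype=float)
    grn = (man["chemistry"] == "Infinium-I") & (man["channel"] == "Green")
    red = (man["chemistry"] == "Infinium-I") & (man["channel"] == "Red")
    two = man["chemistry"] == "Infinium-II"
    out.loc[grn, "green_total"] = df.loc[grn, "MG"] + df.loc[grn, "UG"]
    out.loc[red, "red_total"] = df.loc[red, "MR"] + df.loc[red, "UR"]
    out.loc[two, "green_total"] = df.loc[two, "MG"] + df.loc[two, "UG"]
    out.loc[two, "red_total"] = df.loc[two, "MR"] + df.loc[two, "UR"]
    return out


def _empirical_sf_pvals(x: np.ndarray, oob: np.ndarray) -> np.ndarray:
    """Add-one-smoothed empirical survival p = (#{o >= x} + 1) / (n + 1)."""
    srt = np.sort(oob)
    n = len(srt)
    # number of oob values < x
    below = np.searchsorted(srt, x, side="left")
    return (n - below + 1) / (n + 1)


def pooah(signals: SignalFrame, manifest: Manifest, oob: OOBSet) -> pd.Series:
    """Detection p-values against the out-of-band background (pOOBAH).

    For a measurement with in-band total x in channel c, p_c(x) is the
    add-one empirical survival of x in the channel's OOB vector.
    Infinium-I probes are tested in their design channel; Infinium-II
    probes take the minimum of the two per-channel p-values (methylated
    allele tested in Green, unmethylated in Red).
    """
    totals = _inband_totals(signals, manifest)
    man = manifest.df.loc[signals.df.index]
    p = pd.Series(np.nan, index=signals.df.index, name="detection_p")

    need_green = totals["green_total"].notna().any()
    need_red = totals["red_total"].notna().any()
    if need_green and len(oob.oob_green) == 0:
        raise PreprocessError("empty Green OOB vector; cannot compute detection p")
    if need_red and len(oob.oob_red) == 0:
        raise PreprocessError("empty Red OOB vector; cannot compute detection p")

    has_g = totals["green_total"].notna()
    has_r = totals["red_total"].notna()
    pg = pd.Series(np.nan, index=signals.df.index)
    pr = pd.Series(np.nan, index=signals.df.index)
    if has_g.any():
        pg.loc[has_g] = _empirical_sf_pvals(
            totals.loc[has_g, "green_total"].to_numpy(), oob.oob_green
        )
    if has_r.any():
        pr.loc[has_r] = _empirical_sf_pvals(
            totals.loc[has_r, "red_total"].to_numpy(), oob.oob_red
        )
    two = man["chemistry"] == "Infinium-II"
    p.loc[two] = np.fmin(pg.loc[two], pr.loc[two])
    p.loc[~two & has_g] = pg.loc[~two & has_g]
    p.loc[~two & has_r] = pr.loc[~two & has_r]
    return p


def normexp_conditional_mean(
    x: np.ndarray, mu_b: float, sigma_b: float, alpha: float
) -> np.ndarray:
    """Posterior mean E[s | x] of the true signal under the
    normal-exponential convolution x = s + b, s ~ Exp(alpha),
    b ~ N(mu_b, sigma_b^2).

    E[s|x] = mu_s + sigma_b * phi(mu_s/sigma_b) / Phi(mu_s/sigma_b) with
    mu_s = x - mu_b - sigma_b^2/alpha. Evaluated via the scaled
    complementary error function for numerical stability at mu_s << 0.
    """
    x = np.asarray(x, dtype=float)
    mu_s = x - mu_b - sigma_b**2 / alpha
    z = mu_s / sigma_b
    # phi(z)/Phi(z) = sqrt(2/pi) / erfcx(-z/sqrt(2))
    mills_inv = np.sqrt(2.0 / np.pi) / special.erfcx(-z / np.sqrt(2.0))
    return mu_s + sigma_b * mills_inv


def estimate_normexp_params(
    oob_channel: np.ndarray,
    inband_channel: np.ndarray,
    alpha_floor: float = 10.0,
    sigma_floor: float = 1e-2,
) -> NormexpParams:
    """Method-of-moments normexp parameters: background mean/s.d. from the
    OOB intensities, signal exponential mean from the foreground mean
    excess (floored)."""
    mu_b = float(np.mean(oob_channel))
    sigma_b = float(np.std(oob_channel, ddof=1)) if len(oob_channel) > 1 else 0.0
    if sigma_b <= 0:
        warnings.warn("degenerate OOB distribution (s.d. = 0); using floor")
        sigma_b = sigma_floor
    alpha = max(float(np.mean(inband_channel)) - mu_b, alpha_floor)
    return NormexpParams(mu_b=mu_b, sigma_b=sigma_b, alpha=alpha)


def noob(
    signals: SignalFrame,
    manifest: Manifest,
    oob: OOBSet,
    offset: float = 15.0,
    min_oob: int = 10,
) -> tuple[SignalFrame, dict]:
    """Normal-exponential background subtraction using out-of-band probes.

    Estimates per-channel background parameters from the OOB intensities,
    the signal exponential mean from the in-band mean excess, and replaces
    every intensity by its posterior mean E[s|x] plus a fixed offset; the
    posterior mean is strictly positive, so outputs exceed the offset.

    Returns the corrected SignalFrame and the per-channel parameters.
    """
    for name, vec in (("Green", oob.oob_green), ("Red", oob.oob_red)):
        if len(vec) < min_oob:
            raise PreprocessError(
                f"{name} OOB vector has {len(vec)} values; need >= {min_oob}"
            )
    totals = _inband_totals(signals, manifest)
    inband_green = totals["green_total"].dropna().to_numpy() / 2.0
    inband_red = totals["red_total"].dropna().to_numpy() / 2.0
    params = {
        "Green": estimate_normexp_params(oob.oob_green, inband_green),
        "Red": estimate_normexp_params(oob.oob_red, inband_red),
    }
    out = signals.df.copy()
    for col in ("MG", "UG"):
        p = params["Green"]
        out[col] = normexp_conditional_mean(out[col].to_numpy(), p.mu_b, p.sigma_b, p.alpha) + offset
    for col in ("MR", "UR"):
        p = params["Red"]
        out[col] = normexp_conditional_mean(out[col].to_numpy(), p.mu_b, p.sigma_b, p.alpha) + offset
    return SignalFrame(out), params


def _quantile_map(values: np.ndarray, src_q: np.ndarray, tgt_q: np.ndarray) -> np.ndarray:
    """Monotone map sending the source distribution onto the target:
    piecewise-linear through matched quantile pairs, anchored at (0, 0)
    and extended proportionally beyond the largest source quantile (the
    map is built from Type-I probe totals but applied to allele-level
    intensities, which reach below and above that range)."""
    xs = np.concatenate(([0.0], src_q))
    ys = np.concatenate(([0.0], tgt_q))
    out = np.interp(values, xs, ys)
    high = values > xs[-1]
    if np.any(high) and xs[-1] > 0:
        out[high] = values[high] * (ys[-1] / xs[-1])
    return out


def dyebias_correct(
    signals: SignalFrame,
    manifest: Manifest,
    min_probes: int = 30,
    linear: bool = False,
) -> SignalFrame:
    """Nonlinear (quantile) dye-bias correction between Red and Green.

    Builds empirical quantile functions of the Type-I Red and Type-I Green
    in-band totals, defines the shared target as their quantile-wise
    geometric mean, and maps every Red intensity through
    Q_target(F_red(.)) and every Green intensity analogously. The map is
    monotone non-decreasing and idempotent up to interpolation error.
    ``linear=True`` instead rescales each channel by a single factor
    (median-matching), the simpler variant.
    """
    switch = manifest.df.index[manifest.has_category("channel_switch")]
    red_ids = manifest.type_i_ids("Red").difference(switch).intersection(signals.df.index)
    grn_ids = manifest.type_i_ids("Green").difference(switch).intersection(signals.df.index)
    if len(red_ids) < min_probes or len(grn_ids) < min_probes:
        raise PreprocessError(
            f"need >= {min_probes} Type-I probes per channel for dye-bias "
            f"correction; have Red={len(red_ids)}, Green={len(grn_ids)}"
        )
    df = signals.df
    # allele-level in-band intensities: the map is applied per allele, so
    # its anchor distribution must span the allele intensity range
    red_vals = np.sort(df.loc[red_ids, ["MR", "UR"]].to_numpy().ravel())
    grn_vals = np.sort(df.loc[grn_ids, ["MG", "UG"]].to_numpy().ravel())
    out = df.copy()
    if linear:
        target = np.sqrt(np.median(red_vals) * np.median(grn_vals))
        out[["MR", "UR"]] *= target / np.median(red_vals)
        out[["MG", "UG"]] *= target / np.median(grn_vals)
        return SignalFrame(out)
    # shared target: quantile-wise geometric mean. Anchors are equal-count
    # bin means of the sorted intensities; the per-channel log correction
    # (target over source) is then smoothed across quantile ranks, since
    # dye distortion is a smooth monotone curve while raw matched
    # quantiles from a few hundred probes carry several-percent noise.
    K = min(32, len(red_vals) // 4, len(grn_vals) // 4)
    qr = np.array([b.mean() for b in np.array_split(red_vals, K)])
    qg = np.array([b.mean() for b in np.array_split(grn_vals, K)])
    qt = np.sqrt(qr * qg)
    ranks = np.arange(K, dtype=float)

    def _smooth_target(src: np.ndarray) -> np.ndarray:
        delta = sm_lowess(np.log(qt) - np.log(src), ranks, frac=0.75, it=0,
                          xvals=ranks)
        tgt = src * np.exp(delta)
        return np.maximum.accumulate(tgt)

    tgt_r = _smooth_target(qr)
    tgt_g = _smooth_target(qg)
    for col in ("MR", "UR"):
        out[col] = _quantile_map(out[col].to_numpy(), qr, tgt_r)
    for col in ("MG", "UG"):
        out[col] = _quantile_map(out[col].to_numpy(), qg, tgt_g)
    return SignalFrame(out)


MASK_NONE = "none"
MASK_DETECTION = "detection"
MASK_DEFAULT = "default_mask"


@dataclass
class BetaVector:
    """Per-probe methylation fractions with masking.

    ``beta`` holds values in [0,1] with NaN where masked; ``mask_reason``
    is 'none', 'detection' or 'default_mask' (beta is NaN iff reason is
    not 'none')."""

    beta: pd.Series
    mask_reason: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.beta, "mask_reason": self.mask_reason})


def get_betas(
    signals: SignalFrame,
    manifest: Manifest,
    pvals: pd.Series | None = None,
    p_threshold: float = 0.2,
    apply_default_mask: bool = True,
) -> BetaVector:
    """Summarize corrected signals into β values with masking.

    Infinium-I: β = M/(M+U) using the design channel's alleles;
    Infinium-II: β = MG/(MG+UR). Probes with detection p above
    ``p_threshold`` are masked with reason 'detection'; probes flagged
    mask_default in the manifest (uk / multi-mapping) with reason
    'default_mask' unless ``apply_default_mask`` is False.
    """
    df = signals.df
    man = manifest.df.loc[df.index]
    m = pd.Series(np.nan, index=df.index)
    u = pd.Series(np.nan, index=df.index)
    grn = (man["chemistry"] == "Infinium-I") & (man["channel"] == "Green")
    red = (man["chemistry"] == "Infinium-I") & (man["channel"] == "Red")
    two = man["chemistry"] == "Infinium-II"
    m.loc[grn], u.loc[grn] = df.loc[grn, "MG"], df.loc[grn, "UG"]
    m.loc[red], u.loc[red] = df.loc[red, "MR"], df.loc[red, "UR"]
    m.loc[two], u.loc[two] = df.loc[two, "MG"], df.loc[two, "UR"]
    total = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = m / total
    reason = pd.Series(MASK_NONE, index=df.index)
    undetected = total <= 0
    if pvals is not None:
        undetected |= pvals.reindex(df.index) > p_threshold
    reason.loc[undetected] = MASK_DETECTION
    if apply_default_mask:
        reason.loc[man["mask_default"]] = MASK_DEFAULT
    beta = beta.where(reason == MASK_NONE)
    return BetaVector(beta=beta.rename("beta"), mask_reason=reason.rename("mask_reason"))


def probe_success_rate(pvals: pd.Series, alpha: float = 0.05) -> float:
    """Fraction of probes whose in-band signal significantly exceeds
    background (detection p <= alpha)."""
    p = pvals.dropna()
    if len(p) == 0:
        return float("nan")
    return float((p <= alpha).mean())


class ArrayPreprocessor:
    """End-to-end per-sample preprocessing transform.

    A stateless sklearn-style transformer: ``transform`` runs
    pOOBAH -> noob -> dye-bias -> β on a raw :class:`SignalFrame` and
    returns a :class:`BetaVector`. Detection p-values are computed on the
    raw signals, where comparison against background is meaningful.

    Parameters
    ----------
    manifest : Manifest
    p_threshold : float, default 0.2
        Detection p-value above which a probe's β is masked.
    offset : float, default 15
        Additive offset applied after background subtraction.
    linear_dyebias : bool, default False
        Use the single-factor linear dye-bias variant instead of the
        quantile map.
    apply_default_mask : bool, default True
        Mask uk-prefix / multi-mapping probes.
    """

    def __init__(
        self,
        manifest: Manifest,
        p_threshold: float = 0.2,
        offset: float = 15.0,
        linear_dyebias: bool = False,
        apply_default_mask: bool = True,
    ):
        self.manifest = manifest
        self.p_threshold = p_threshold
        self.offset = offset
        self.linear_dyebias = linear_dyebias
        self.apply_default_mask = apply_default_mask

    def get_params(self, deep: bool = True) -> dict:
        return {
            "manifest": self.manifest,
            "p_threshold": self.p_threshold,
            "offset": self.offset,
            "linear_dyebias": self.linear_dyebias,
            "apply_default_mask": self.apply_default_mask,
        }

    def set_params(self, **params) -> "ArrayPreprocessor":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "ArrayPreprocessor":
        return self

    def transform(self, signals: SignalFrame) -> BetaVector:
        beta, _ = self.transform_detailed(signals)
        return beta

    def transform_detailed(self, signals: SignalFrame):
        """Run the pipeline and also return intermediates
        (pvals, corrected signals, normexp params)."""
        oob = extract_oob(signals, self.manifest)
        pvals = pooah(signals, self.manifest, oob)
        corrected, params = noob(signals, self.manifest, oob, offset=self.offset)
        corrected = dyebias_correct(corrected, self.manifest, linear=self.linear_dyebias)
        beta = get_betas(
            corrected,
            self.manifest,
            pvals,
            p_threshold=self.p_threshold,
            apply_default_mask=self.apply_default_mask,
        )
        return beta, {"pvals": pvals, "corrected": corrected, "normexp": params}


def process_sample(signals: SignalFrame, manifest: Manifest, **kwargs) -> BetaVector:
    """Functional wrapper over :class:`ArrayPreprocessor`."""
    return ArrayPreprocessor(manifest, **kwargs).transform(signals)
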