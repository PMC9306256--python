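"""SNP-probe strain genotyping, mixture detection, and backcross tracing.

The array carries SNP probes targeting clade-segregating variants of
common inbred mouse strains. Each probe's two allele signals yield a
variant allele fraction (VAF); comparing VAF profiles against a strain
genotype reference with a Gaussian observation model gives a
maximum-likelihood strain call, two-strain mixture detection (F1 hybrids,
contaminations), and the donor allele fraction tracking backcross
progress (expected 0.5^(n+1) at backcross generation n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .manifest import Manifest
from .preprocess import SignalFrame


class StrainError(ValueError):
    pass


@dataclass
class StrainReference:
    """Genotype matrix G[strain, snp] with entries 0 (reference-allele
    homozygous), 1 (alternate homozygous), NaN (missing)."""

    genotypes: pd.DataFrame  # strains x snps

    def __post_init__(self) -> None:
        if len(self.genotypes) < 2:
            raise StrainError("need at least two strains in the reference")
        vals = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0) | (vals == 1)
        if not ok.all():
            raise StrainError("genotypes must be 0, 1 or missing")

    @property
    def strains(self) -> pd.Index:
        return self.genotypes.index

    @property
    def snps(self) -> pd.Index:
        return self.genotypes.columns

    @classmethod
    def from_manifest(cls, manifest: Manifest) -> "StrainReference":
        return cls(manifest.strain_genotypes())

    @classmethod
    def from_tsv(cls, path) -> "StrainReference":
        df = pd.read_csv(path, sep="\t").set_index("snp_id")
        return cls(df.T.astype(float))

    def to_tsv(self, path) -> None:
        out = self.genotypes.T.reset_index(names="snp_id")
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class StrainCall:
    """Result of maximum-likelihood strain classification."""

    best_strain: str
    loglik: pd.Series  # per candidate strain
    margin: float  # best minus runner-up log-likelihood
    tau: float
    mixture: tuple | None = None  # (strain_a, strain_b, pi) if detected


def snp_vaf(
    signals: SignalFrame,
    manifest: Manifest,
    pvals: pd.Series | None = None,
    p_threshold: float = 0.2,
) -> pd.Series:
    """Alternate-allele signal fraction per SNP probe.

    The alternate allele occupies the methylated-allele slot of the probe
    design, so v = alt/(ref+alt) follows the same channel arithmetic as a
    β value: design-channel M/(M+U) for Infinium-I, MG/(MG+UR) for
    Infinium-II. Probes failing detection (p > threshold) or with zero
    total are missing.
    """
    man = manifest.df
    snp_ids = man.index[man["target"] == "SNP"].intersection(signals.df.index)
    if len(snp_ids) == 0:
        raise StrainError("no SNP probes present in signals")
    df = signals.df.loc[snp_ids]
    sub = man.loc[snp_ids]
    alt = pd.Series(np.nan, index=snp_ids)
    ref = pd.Series(np.nan, index=snp_ids)
    grn = (sub["chemistry"] == "Infinium-I") & (sub["channel"] == "Green")
    red = (sub["chemistry"] == "Infinium-I") & (sub["channel"] == "Red")
    two = sub["chemistry"] == "Infinium-II"
    alt.loc[grn], ref.loc[grn] = df.loc[grn, "MG"], df.loc[grn, "UG"]
    alt.loc[red], ref.loc[red] = df.loc[red, "MR"], df.loc[red, "UR"]
    alt.loc[two], ref.loc[two] = df.loc[two, "MG"], df.loc[two, "UR"]
    total = alt + ref
    with np.errstate(invalid="ignore", divide="ignore"):
        v = (alt / total).where(total > 0)
    if pvals is not None:
        v = v.where(pvals.reindex(snp_ids) <= p_threshold)
    return v.rename("vaf")


def _censored_norm_logpdf(v: np.ndarray, g: np.ndarray, tau: float) -> np.ndarray:
    """Log-likelihood under v = clip(w, 0, 1), w ~ N(g, tau^2).

    Interior observations use the Gaussian density; observations exactly
    at a boundary use the censored tail mass (allele fractions are
    ratios, so noise piles up at 0 and 1 rather than crossing them)."""
    out = stats.norm.logpdf(v, loc=g, scale=tau)
    at1 = v >= 1.0
    at0 = v <= 0.0
    if at1.any():
        out[at1] = stats.norm.logsf(1.0, loc=g[at1], scale=tau)
    if at0.any():
        out[at0] = stats.norm.logcdf(0.0, loc=g[at0], scale=tau)
    return out


def strain_loglik(v: pd.Series, g: pd.Series, tau: float = 0.1) -> float:
    """Boundary-censored Gaussian log-likelihood of an observed VAF
    vector given expected allele fractions g (0, 0.5 or 1 per SNP);
    missing entries on either side are skipped."""
    common = v.index.intersection(g.index)
    vv = v.reindex(common).to_numpy(dtype=float)
    gg = g.reindex(common).to_numpy(dtype=float)
    keep = ~(np.isnan(vv) | np.isnan(gg))
    if not keep.any():
        raise StrainError("no overlapping non-missing SNPs between VAF and genotype")
    return float(np.sum(_censored_norm_logpdf(vv[keep], gg[keep], tau)))


def classify_strain(
    v: pd.Series,
    ref: StrainReference,
    tau: float = 0.1,
    check_mixture: bool = False,
    delta_threshold: float = 2.0,
) -> StrainCall:
    """Maximum-likelihood strain call; ties broken lexicographically."""
    logliks = pd.Series(
        {s: strain_loglik(v, ref.genotypes.loc[s], tau=tau) for s in ref.strains}
    ).sort_index()
    order = logliks.sort_values(ascending=False, kind="stable")
    best = order.index[0]
    if len(order) > 1 and np.isclose(order.iloc[0], order.iloc[1]):
        tied = order.index[np.isclose(order.to_numpy(), order.iloc[0])]
        best = sorted(tied)[0]
        warnings.warn(f"tied strain likelihoods among {sorted(tied)}; chose {best}")
    margin = float(order.iloc[0] - order.iloc[1]) if len(order) > 1 else float("inf")
    mixture = None
    if check_mixture:
        mixture = detect_mixture(v, ref, tau=tau, delta_threshold=delta_threshold)
    return StrainCall(
        best_strain=str(best), loglik=logliks, margin=max(margin, 0.0), tau=tau,
        mixture=mixture,
    )


def detect_mixture(
    v: pd.Series,
    ref: StrainReference,
    tau: float = 0.1,
    grid_step: float = 0.01,
    delta_threshold: float = 2.0,
) -> tuple | None:
    """Two-strain mixture search.

    Maximizes the likelihood of expected fractions pi*g_A + (1-pi)*g_B
    over ordered strain pairs and pi on a grid; reports (A, B, pi) iff the
    mixture log-likelihood beats the best single-strain log-likelihood by
    more than ``delta_threshold`` per comparison — i.e. the maximized
    mixture likelihood must clear the single-strain likelihood by
    ``delta_threshold`` plus log(#pairs x #grid points), which accounts
    for the selection over all candidate mixtures. The grid covers
    pi in [0.05, 0.95]: a component below 5% is indistinguishable from
    boundary noise (observed fractions are clipped to [0, 1]), so more
    extreme mixtures are not searched.
    """
    strains = list(ref.strains)
    common = v.index.intersection(ref.snps)
    vv = v.reindex(common).to_numpy(dtype=float)
    G = ref.genotypes[common].to_numpy(dtype=float)
    keep = ~np.isnan(vv)
    vv = vv[keep]
    G = G[:, keep]
    if vv.size == 0:
        raise StrainError("no non-missing SNPs for mixture detection")
    pis = np.arange(0.05, 0.95 + grid_step / 2, grid_step)

    def _ll(expected: np.ndarray) -> float:
        ok = ~np.isnan(expected)
        return float(np.sum(_censored_norm_logpdf(vv[ok], expected[ok], tau)))

    best_single = max(_ll(G[i]) for i in range(len(strains)))
    best_mix = (-np.inf, None)
    for i in range(len(strains)):
        for j in range(i + 1, len(strains)):
            # vectorize over the pi grid
            exp_all = pis[:, None] * G[i][None, :] + (1 - pis[:, None]) * G[j][None, :]
            ok = ~np.isnan(exp_all)
            vmat = np.broadcast_to(vv[None, :], exp_all.shape)
            lls = np.where(
                ok,
                _censored_norm_logpdf(vmat.ravel(), np.nan_to_num(exp_all).ravel(), tau
                                      ).reshape(exp_all.shape),
                0.0,
            ).sum(axis=1)
            k = int(np.argmax(lls))
            if lls[k] > best_mix[0]:
                best_mix = (float(lls[k]), (strains[i], strains[j], float(pis[k])))
    n_pairs = len(strains) * (len(strains) - 1) // 2
    selection_penalty = np.log(max(n_pairs * len(pis), 1))
    if best_mix[0] > best_single + delta_threshold + selection_penalty:
        a, b, pi = best_mix[1]
        # interior pi only: pi in {0,1} is a single strain, not a mixture
        if grid_step / 2 < pi < 1 - grid_step / 2:
            return (a, b, pi)
    return None


def backcross_fraction(
    v: pd.Series,
    segregating_snps,
    donor_is_alt: pd.Series | bool = True,
    het_low: float = 0.25,
    het_high: float = 0.75,
) -> tuple[float, pd.Series]:
    """Donor allele fraction and per-SNP genotype calls for a backcross.

    ``segregating_snps`` selects the SNPs distinguishing donor from
    recipient; ``donor_is_alt`` says (per SNP or globally) whether the
    donor carries the alternate allele there, orienting v toward the
    donor. Calls: donor-hom above ``het_high``, het in between
    (inclusive), recipient-hom below ``het_low``. The fraction is the mean
    donor-oriented VAF over non-missing SNPs.
    """
    snps = pd.Index(segregating_snps)
    if len(snps) == 0:
        raise StrainError("empty segregating SNP set")
    vd = v.reindex(snps).astype(float)
    if isinstance(donor_is_alt, pd.Series):
        flip = ~donor_is_alt.reindex(snps).astype(bool)
        vd = vd.where(~flip, 1.0 - vd)
    elif not donor_is_alt:
        vd = 1.0 - vd
    calls = pd.Series("missing", index=snps, name="genotype_call")
    ok = vd.notna()
    calls.loc[ok & (vd > het_high)] = "donor-hom"
    calls.loc[ok & (vd >= het_low) & (vd <= het_high)] = "het"
    calls.loc[ok & (vd < het_low)] = "recipient-hom"
    if not ok.any():
        raise StrainError("all segregating SNPs are missing")
    return float(vd[ok].mean()), calls


class StrainClassifier:
    """sklearn-style maximum-likelihood strain classifier.

    ``fit(G, y)`` takes a genotype matrix (n_strains x n_snps as a
    DataFrame with SNP columns) and strain labels; ``predict(V)`` returns
    the best strain per VAF row; ``predict_margin`` the log-likelihood
    margins.

    Parameters
    ----------
    tau : float, default 0.1
        Observation noise s.d. around the expected allele fraction.
    """

    def __init__(self, tau: float = 0.1):
        self.tau = tau

    def get_params(self, deep: bool = True) -> dict:
        return {"tau": self.tau}

    def set_params(self, **params) -> "StrainClassifier":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, G: pd.DataFrame, y=None) -> "StrainClassifier":
        labels = pd.Index(y) if y is not None else G.index
        self.reference_ = StrainReference(pd.DataFrame(
            np.asarray(G, dtype=float), index=labels,
            columns=G.columns if isinstance(G, pd.DataFrame) else None,
        ))
        self.classes_ = np.array(sorted(self.reference_.strains))
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "reference_"):
            raise StrainError("classifier is not fitted; call fit() first")

    def _as_frame(self, V) -> pd.DataFrame:
        if isinstance(V, pd.Series):
            V = V.to_frame().T
        if not isinstance(V, pd.DataFrame):
            V = pd.DataFrame(np.atleast_2d(np.asarray(V, dtype=float)),
                             columns=self.reference_.snps)
        return V

    def predict(self, V) -> np.ndarray:
        self._check_fitted()
        V = self._as_frame(V)
        return np.array([
            classify_strain(row, self.reference_, tau=self.tau).best_strain
            for _, row in V.iterrows()
        ])

    def predict_call(self, v: pd.Series, **kwargs) -> StrainCall:
        self._check_fitted()
        return classify_strain(v, self.reference_, tau=self.tau, **kwargs)

    def score(self, V, y) -> float:
        pred = self.predict(V)
        return float(np.mean(pred == np.asarray(y)))
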