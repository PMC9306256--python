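"""Differential methylation and downstream locus interpretation.

Mass-univariate statistics on a β matrix (probes x samples):

* multivariate OLS per probe with per-term F-tests and delta-β effect
  sizes, Benjamini-Hochberg adjusted across probes;
* one-vs-rest tissue signatures (perfectly discriminating probes ranked
  by methylation difference, top K per direction);
* human-mouse tissue/species effect decomposition;
* Fisher exact region-set enrichment with fixed windows centered on the
  query CpGs;
* regulatory-potential-based target-gene selection around CpGs;
* mono-allelic methylation group calling (Groups I-IV of increasing
  stringency: intermediate in soma, polarized in testis, located in
  imprinting-associated regions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .manifest import RegionSet


class DiffMethError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Multivariate regression with F-tests
# ---------------------------------------------------------------------------

@dataclass
class DMLResult:
    """Per-probe, per-term regression results.

    ``tables[term]`` has columns F, p, q (BH across probes), effect
    (delta-β: adjusted max-min level difference for categorical terms,
    |slope| x predictor range for continuous ones) and coef (the single
    term coefficient where the term has one column, else NaN).
    """

    tables: dict
    terms: list
    n_samples: int
    coefficients: pd.DataFrame | None = None

    def __getitem__(self, term: str) -> pd.DataFrame:
        return self.tables[term]


def _build_design(annot: pd.DataFrame, terms: list[str]):
    """Design matrix with intercept; returns (X, term -> column indices,
    term metadata)."""
    cols = [pd.Series(1.0, index=annot.index, name="Intercept")]
    term_cols: dict = {}
    term_info: dict = {}
    j = 1
    for term in terms:
        x = annot[term]
        if pd.api.types.is_numeric_dtype(x) and not pd.api.types.is_bool_dtype(x):
            cols.append(x.astype(float).rename(term))
            term_cols[term] = [j]
            term_info[term] = {"kind": "continuous", "range": float(x.max() - x.min())}
            j += 1
        else:
            xc = x.astype("category") if not pd.api.types.is_bool_dtype(x) else x.map({False: "0", True: "1"}).astype("category")
            levels = list(xc.cat.categories)
            if len(levels) < 2:
                raise DiffMethError(f"term {term!r} has fewer than two levels")
            dummies = pd.get_dummies(xc, prefix=term, drop_first=True).astype(float)
            cols.append(dummies)
            term_cols[term] = list(range(j, j + dummies.shape[1]))
            term_info[term] = {"kind": "categorical", "levels": levels}
            j += dummies.shape[1]
    X = pd.concat(cols, axis=1)
    return X.to_numpy(dtype=float), term_cols, term_info, list(X.columns)


def _ols_rss(X: np.ndarray, Y: np.ndarray):
    """Least-squares fit of every column of Y on X; returns (coef, rss)."""
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return coef, np.sum(resid**2, axis=0), rank


def fit_dml(
    betas: pd.DataFrame,
    annot: pd.DataFrame,
    terms: list[str],
) -> DMLResult:
    """Multivariate OLS of β on additive predictors with per-term F-tests.

    ``betas`` is probes x samples; ``annot`` is indexed by sample and must
    contain every term column. For each term the F statistic compares the
    full model with the model omitting that term; p-values come from the
    F distribution and are BH-adjusted across probes within each term.
    Probes with missing β are fitted per-probe on their complete cases;
    probes whose design becomes rank-deficient get missing results with a
    warning.
    """
    samples = betas.columns.intersection(annot.index)
    if len(samples) < len(betas.columns):
        warnings.warn("dropping samples absent from the annotation")
    betas = betas[samples]
    annot = annot.loc[samples]
    X, term_cols, term_info, _ = _build_design(annot, terms)
    n, p_full = X.shape
    if n <= p_full:
        raise DiffMethError(f"need more samples ({n}) than parameters ({p_full})")

    Y = betas.T.to_numpy(dtype=float)  # samples x probes
    probes = betas.index
    complete = ~np.isnan(Y).any(axis=0)

    F = {t: np.full(len(probes), np.nan) for t in terms}
    P = {t: np.full(len(probes), np.nan) for t in terms}
    EFF = {t: np.full(len(probes), np.nan) for t in terms}
    COEF = {t: np.full(len(probes), np.nan) for t in terms}

    def _fill(idx: np.ndarray, Xs: np.ndarray, Ys: np.ndarray) -> None:
        ns = Xs.shape[0]
        coef_full, rss_full, rank = _ols_rss(Xs, Ys)
        if rank < Xs.shape[1]:
            warnings.warn("rank-deficient design; affected probes get missing results")
            return
        df2 = ns - Xs.shape[1]
        for t in terms:
            keep = [j for j in range(Xs.shape[1]) if j not in term_cols[t]]
            _, rss_red, _ = _ols_rss(Xs[:, keep], Ys)
            df1 = len(term_cols[t])
            with np.errstate(invalid="ignore", divide="ignore"):
                f = ((rss_red - rss_full) / df1) / (rss_full / df2)
            f = np.where(np.isfinite(f), np.maximum(f, 0.0), 0.0)
            F[t][idx] = f
            P[t][idx] = stats.f.sf(f, df1, df2)
            cj = coef_full[term_cols[t], :]
            if term_info[t]["kind"] == "continuous":
                EFF[t][idx] = np.abs(cj[0]) * term_info[t]["range"]
                COEF[t][idx] = cj[0]
            else:
                # adjusted level means differ from baseline by the dummy
                # coefficients; baseline itself contributes 0
                with_base = np.vstack([np.zeros(cj.shape[1]), cj])
                EFF[t][idx] = with_base.max(axis=0) - with_base.min(axis=0)
                if cj.shape[0] == 1:
                    COEF[t][idx] = cj[0]

    if complete.any():
        _fill(np.flatnonzero(complete), X, Y[:, complete])
    for i in np.flatnonzero(~complete):
        ok = ~np.isnan(Y[:, i])
        if ok.sum() <= p_full:
            warnings.warn("probe with too few complete cases; missing result")
            continue
        _fill(np.array([i]), X[ok], Y[ok][:, [i]])

    tables = {}
    for t in terms:
        q = np.full(len(probes), np.nan)
        ok = ~np.isnan(P[t])
        if ok.any():
            q[ok] = multipletests(P[t][ok], method="fdr_bh")[1]
        tables[t] = pd.DataFrame(
            {"F": F[t], "p": P[t], "q": q, "effect": EFF[t], "coef": COEF[t]},
            index=probes,
        )
    return DMLResult(tables=tables, terms=list(terms), n_samples=n)


def call_significant(
    result: DMLResult,
    p_max: float = 0.05,
    effect_min: float = 0.1,
    adjusted: bool = False,
    signed: bool = False,
) -> dict:
    """Threshold a DMLResult into per-term significant probe sets.

    Default (tissue mode): raw p < p_max and effect (delta-β) > effect_min.
    ``adjusted=True`` thresholds the BH-adjusted q instead (tumor/age
    mode: q < 0.01, |coef| > 0.1). With ``signed=True`` each term's set is
    split by the sign of its coefficient into ``(term, 'hyper')`` /
    ``(term, 'hypo')`` entries (single-coefficient terms only).
    """
    out: dict = {}
    for t in result.terms:
        tab = result[t]
        pcol = tab["q"] if adjusted else tab["p"]
        sig = (pcol < p_max) & (tab["effect"] > effect_min)
        sig = sig.fillna(False)
        if signed:
            if tab["coef"].isna().all():
                raise DiffMethError(
                    f"term {t!r} has no single coefficient; cannot sign calls"
                )
            out[(t, "hyper")] = tab.index[sig & (tab["coef"] > 0)]
            out[(t, "hypo")] = tab.index[sig & (tab["coef"] < 0)]
        else:
            out[t] = tab.index[sig]
    return out


def filter_probes(
    betas: pd.DataFrame,
    coords: pd.DataFrame | None = None,
    max_missing: float = 0.25,
    beta_max_min: float = 0.2,
    beta_min_max: float = 0.8,
    exclude_chroms: tuple = ("chrX", "chrY", "X", "Y"),
) -> pd.DataFrame:
    """Standard pre-filter for the tumor/age regression mode.

    Drops sex-chromosome probes, probes missing in more than
    ``max_missing`` of the samples, and constitutive probes
    (max β < ``beta_max_min`` or min β > ``beta_min_max``).
    """
    keep = pd.Series(True, index=betas.index)
    if coords is not None:
        chrom = coords["chrom"].reindex(betas.index)
        keep &= ~chrom.isin(exclude_chroms)
    keep &= betas.isna().mean(axis=1) <= max_missing
    mx = betas.max(axis=1)
    mn = betas.min(axis=1)
    keep &= ~((mx < beta_max_min) | (mn > beta_min_max))
    return betas.loc[keep]


# ---------------------------------------------------------------------------
# One-vs-rest tissue signatures
# ---------------------------------------------------------------------------

def auc_one_vs_rest(values, is_target) -> float:
    """Mann-Whitney AUC for discriminating target samples from the rest
    at one probe, ties counted 0.5."""
    values = np.asarray(values, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    n1 = int(is_target.sum())
    n0 = int((~is_target).sum())
    if n1 == 0 or n0 == 0:
        raise DiffMethError("both groups must be non-empty for AUC")
    ranks = stats.rankdata(values)
    u = ranks[is_target].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


@dataclass
class SignatureSet:
    """A tissue's hyper- or hypomethylation signature: probes that
    perfectly discriminate the tissue, ranked by methylation difference."""

    tissue: str
    direction: str  # 'hyper' | 'hypo'
    probes: list
    differences: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def tissue_signature(
    betas: pd.DataFrame,
    annot: pd.DataFrame,
    target_tissue: str,
    tissue_col: str = "tissue",
    K: int = 200,
) -> tuple[SignatureSet, SignatureSet]:
    """One-vs-rest signatures for one tissue.

    Candidates are probes whose β values strictly separate the target
    samples from the rest (AUC exactly 1 for hyper, 0 for hypo); they are
    ranked by |mean(target) - mean(rest)| descending (ties broken by
    probe ID) and the top K per direction returned.
    """
    samples = betas.columns.intersection(annot.index)
    betas = betas[samples]
    is_target = (annot.loc[samples, tissue_col] == target_tissue).to_numpy()
    if is_target.sum() < 2 or (~is_target).sum() < 2:
        raise DiffMethError("need >= 2 samples in the target tissue and in the rest")
    sub = betas.dropna(axis=0)
    tgt = sub.loc[:, is_target].to_numpy()
    rest = sub.loc[:, ~is_target].to_numpy()
    # AUC == 1 iff every target value exceeds every rest value
    hyper = tgt.min(axis=1) > rest.max(axis=1)
    hypo = tgt.max(axis=1) < rest.min(axis=1)
    diff = pd.Series(tgt.mean(axis=1) - rest.mean(axis=1), index=sub.index)

    def _top(mask: np.ndarray, direction: str) -> SignatureSet:
        d = diff[mask].abs()
        order = pd.DataFrame({"d": d, "id": d.index}).sort_values(
            ["d", "id"], ascending=[False, True]
        )
        sel = order.index[:K]
        return SignatureSet(
            tissue=target_tissue,
            direction=direction,
            probes=list(sel),
            differences=diff.loc[sel],
        )

    return _top(hyper, "hyper"), _top(hypo, "hypo")


# ---------------------------------------------------------------------------
# Tissue / species effect decomposition
# ---------------------------------------------------------------------------

def decompose_tissue_species(
    betas: pd.DataFrame,
    annot: pd.DataFrame,
    tissue_col: str = "tissue",
    species_col: str = "species",
    effect_min: float = 0.4,
    ratio_min: float = 3.0,
) -> pd.DataFrame:
    """Per-probe tissue- vs species-effect decomposition on syntenic CpGs.

    Cell means are computed for every tissue x species combination; the
    tissue effect is max - min of the tissue marginal means (averaging
    cells over species) and the species effect the analogue over species.
    A probe is labelled ``species-specific`` iff species effect >
    ``effect_min`` and species/tissue ratio > ``ratio_min``;
    ``tissue-specific`` symmetrically; else ``none``.
    """
    samples = betas.columns.intersection(annot.index)
    betas = betas[samples]
    ann = annot.loc[samples]
    tissues = ann[tissue_col].unique()
    species = ann[species_col].unique()
    if len(tissues) < 2 or len(species) < 2:
        raise DiffMethError("need >= 2 tissues and >= 2 species")
    cells = {}
    for ti in tissues:
        for sp in species:
            cols = samples[(ann[tissue_col] == ti) & (ann[species_col] == sp)]
            if len(cols) == 0:
                warnings.warn(f"no samples for cell ({ti}, {sp}); using available cells")
                continue
            cells[(ti, sp)] = betas[cols].mean(axis=1)
    cell_df = pd.DataFrame(cells)
    tissue_means = cell_df.T.groupby(level=0).mean().T
    species_means = cell_df.T.groupby(level=1).mean().T
    tissue_eff = tissue_means.max(axis=1) - tissue_means.min(axis=1)
    species_eff = species_means.max(axis=1) - species_means.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sp_ratio = species_eff / tissue_eff
        ti_ratio = tissue_eff / species_eff
    label = pd.Series("none", index=betas.index)
    label[(species_eff > effect_min) & (sp_ratio > ratio_min)] = "species-specific"
    label[(tissue_eff > effect_min) & (ti_ratio > ratio_min)] = "tissue-specific"
    return pd.DataFrame(
        {"tissue_effect": tissue_eff, "species_effect": species_eff, "label": label}
    )


# ---------------------------------------------------------------------------
# Region-set enrichment
# ---------------------------------------------------------------------------

def region_enrichment(
    query_cpgs,
    background_cpgs,
    coords: pd.DataFrame,
    region_sets: list[RegionSet],
    window: int = 200,
) -> pd.DataFrame:
    """Fisher exact enrichment of query CpGs in region sets.

    A CpG contributes through the fixed-width window centered on it
    ([pos - w/2, pos + w/2) in 0-based coordinates). For each set,
    a = query CpGs overlapping, b = query not overlapping, c/d the same
    on background minus query. The odds ratio uses a 0.5 continuity
    correction only when a zero cell occurs (flagged); p-values are
    two-sided Fisher exact, BH-adjusted across sets.
    """
    query = pd.Index(query_cpgs)
    background = pd.Index(background_cpgs)
    if len(background) == 0:
        raise DiffMethError("empty background")
    if not query.isin(background).all():
        raise DiffMethError("query CpGs must be a subset of the background")
    rest = background.difference(query)
    half = window // 2

    def _hits(ids: pd.Index, rs: RegionSet) -> int:
        sub = coords.loc[ids]
        pos0 = sub["pos"].to_numpy(dtype=int) - 1  # manifest is 1-based
        starts = pos0 - half
        ends = starts + window
        return int(rs.overlaps_many(sub["chrom"].tolist(), starts, ends).sum())

    rows = []
    for rs in region_sets:
        a = _hits(query, rs)
        b = len(query) - a
        c = _hits(rest, rs)
        d = len(rest) - c
        zero = 0 in (a, b, c, d)
        if (a == 0 and c == 0) or (b == 0 and d == 0):
            oddsr = 1.0  # no overlaps (or all overlaps) anywhere: uninformative
        elif zero:
            oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            oddsr = (a * d) / (b * c)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {"region_set": rs.name, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": oddsr, "p": p, "continuity_corrected": zero}
        )
    out = pd.DataFrame(rows).set_index("region_set")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out


# ---------------------------------------------------------------------------
# RP-score target-gene selection
# ---------------------------------------------------------------------------

def select_target_genes(
    cpg_coords: pd.DataFrame,
    tss_table: pd.DataFrame,
    rp_scores: pd.DataFrame,
    required_factors,
    n_per_side: int = 10,
    max_dist: int = 1_000_000,
    rp_min: float = 2.0,
) -> list:
    """Putative target genes of CpG sites, filtered by regulatory
    potential.

    Candidates are, per CpG, the up-to-``n_per_side`` nearest gene TSSs
    within ``max_dist`` on each side. A candidate is retained iff for
    *every* required factor at least one ChIP-seq experiment assigns it an
    RP score above ``rp_min``; genes absent from the RP table fail that
    factor.
    """
    candidates: set = set()
    for _, row in cpg_coords.iterrows():
        genes = tss_table[tss_table["chrom"] == row["chrom"]].copy()
        genes["dist"] = genes["tss"] - row["pos"]
        near = genes[genes["dist"].abs() <= max_dist]
        up = near[near["dist"] < 0].nlargest(n_per_side, "dist")
        down = near[near["dist"] >= 0].nsmallest(n_per_side, "dist")
        candidates.update(up["gene"])
        candidates.update(down["gene"])
    best = rp_scores.groupby(["gene", "factor"])["score"].max()
    selected = []
    for gene in sorted(candidates):
        ok = all(
            (gene, f) in best.index and best.loc[(gene, f)] > rp_min
            for f in required_factors
        )
        if ok:
            selected.append(gene)
    return selected


# ---------------------------------------------------------------------------
# Mono-allelic methylation groups
# ---------------------------------------------------------------------------

MONOALLELIC_GROUPS = ("none", "I", "II", "III", "IV")


def classify_monoallelic(
    betas: pd.DataFrame,
    annot: pd.DataFrame,
    coords: pd.DataFrame,
    icr: RegionSet,
    sdmr: RegionSet,
    compartment_col: str = "compartment",
    beta_low: float = 0.3,
    beta_high: float = 0.7,
    frac_group_i: float = 0.5,
    frac_group_ii: float = 0.9,
) -> pd.Series:
    """Call mono-allelic methylation groups per probe.

    Group I: intermediately methylated (beta_low < β < beta_high) in more
    than ``frac_group_i`` of somatic samples. Group II: intermediate in
    more than ``frac_group_ii`` of somatic samples AND polarized
    (β > beta_high or β < beta_low) in every testis sample. Group III:
    II and located in ICR ∪ sDMR; Group IV: II and located in an ICR.
    The highest applicable group is reported; the groups nest
    IV ⊆ III ⊆ II ⊆ I by construction.
    """
    samples = betas.columns.intersection(annot.index)
    comp = annot.loc[samples, compartment_col]
    somatic = samples[comp == "somatic"]
    testis = samples[comp == "testis"]
    if len(somatic) == 0:
        raise DiffMethError("no somatic samples annotated")
    if len(testis) == 0:
        warnings.warn("no testis samples; groups II-IV unavailable")

    soma = betas[somatic]
    inter = (soma > beta_low) & (soma < beta_high)
    nobs = soma.notna().sum(axis=1)
    frac = inter.sum(axis=1) / nobs.replace(0, np.nan)
    g1 = frac > frac_group_i
    if len(testis) > 0:
        tes = betas[testis]
        polarized = ((tes > beta_high) | (tes < beta_low)) | tes.isna()
        all_polarized = polarized.all(axis=1) & tes.notna().any(axis=1)
        g2 = (frac > frac_group_ii) & all_polarized
    else:
        g2 = pd.Series(False, index=betas.index)
    pos0 = coords["pos"].reindex(betas.index).astype(float) - 1
    chrom = coords["chrom"].reindex(betas.index)
    in_icr = pd.Series(
        [
            icr.overlaps(c, int(p), int(p) + 1) if pd.notna(p) else False
            for c, p in zip(chrom, pos0)
        ],
        index=betas.index,
    )
    in_sdmr = pd.Series(
        [
            sdmr.overlaps(c, int(p), int(p) + 1) if pd.notna(p) else False
            for c, p in zip(chrom, pos0)
        ],
        index=betas.index,
    )
    g3 = g2 & (in_icr | in_sdmr)
    g4 = g2 & in_icr
    label = pd.Series("none", index=betas.index, name="monoallelic_group")
    label[g1.fillna(False)] = "I"
    label[g2.fillna(False) & g1.fillna(False)] = "II"
    label[g3.fillna(False) & g1.fillna(False)] = "III"
    label[g4.fillna(False) & g1.fillna(False)] = "IV"
    return label


def monoallelic_design_screen(
    betas: pd.DataFrame,
    beta_low: float = 0.35,
    beta_high: float = 0.65,
    frac_min: float = 0.65,
    min_samples: int = 7,
) -> pd.Series:
    """Design-phase mono-allelic candidate screen: probes intermediately
    methylated (0.35-0.65) in over 65% of samples, with more than six
    samples observed."""
    inter = (betas > beta_low) & (betas < beta_high)
    nobs = betas.notna().sum(axis=1)
    frac = inter.sum(axis=1) / nobs.replace(0, np.nan)
    return ((nobs >= min_samples) & (frac > frac_min)).rename("monoallelic_candidate")
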