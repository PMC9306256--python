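"""Synthetic manifests, methylomes, and two-channel signals.

The generators emulate the statistical structure the pipeline assumes:
Infinium-I probes of both color channels (their opposite channel drawing
background-only fluorescence), Infinium-II probes, normal background plus
exponential signal intensities with a multiplicative Red dye factor,
tissue/age/sex methylome structure, imprinted probes intermediate in soma
and polarized in testis, strain-clade SNP genotypes, methylation
titrations, human-mouse species mixtures, per-SNP backcross inheritance,
and a binomial low-input dropout mode. Every simulated observable is
recorded in a truth table so estimator tests can compare against ground
truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .manifest import Manifest
from .preprocess import SignalFrame
from .strains import StrainReference


class SynthError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the simulators.

    Probe counts mirror a miniature array (hundreds of probes instead of
    hundreds of thousands); signal parameters follow the
    normal-background + exponential-signal model the background
    correction assumes. The 19 channel-switch probes match the count of
    human-mouse variant probes on the real array; the 11 titration
    fractions are the printed calibration design.
    """

    seed: int = 0
    # probe counts by category
    n_cg_i_red: int = 100
    n_cg_i_grn: int = 100
    n_cg_ii: int = 800
    n_ch: int = 20
    n_channel_switch: int = 19
    n_control: int = 10
    n_uk: int = 5
    # signal model (arbitrary fluorescence units)
    bg_mean: float = 500.0
    bg_sd: float = 100.0
    signal_mean: float = 3000.0
    gain: float = 1.0
    dye_factor: float = 1.0
    # methylome structure
    tissues: tuple = ("liver", "colon", "blood", "testis")
    n_per_tissue: int = 5
    n_tissue_markers: int = 40  # per tissue per direction
    n_age_probes: int = 50
    n_imprint_probes: int = 30
    tissue_delta: float = 0.5
    age_slope: float = 0.02  # beta units per month
    age_range_months: tuple = (1.0, 24.0)
    beta_noise_sd: float = 0.02
    # strain panel
    strains: tuple = ()
    snps_per_branch: int = 4
    # low-input mode
    n_template_molecules: int | None = None

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthTables:
    """Ground truth for every simulated observable."""

    true_betas: pd.DataFrame | None = None  # probes x samples
    probe_roles: pd.DataFrame | None = None
    annot: pd.DataFrame | None = None
    human_fractions: dict = field(default_factory=dict)
    genotypes: pd.DataFrame | None = None  # strains x snps


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def _strain_branches(strains: list[str]) -> list[tuple[str, list[str]]]:
    """Clades of a balanced binary phylogeny over the strains: every
    internal node below the root plus every leaf is a branch whose
    descendant strains share that branch's alternate alleles."""
    branches: list[tuple[str, list[str]]] = []

    def rec(group: list[str]) -> None:
        if len(group) == 1:
            branches.append((group[0], group))
            return
        branches.append(("+".join(group[:2]) + f"..n{len(group)}", group))
        mid = len(group) // 2
        rec(group[:mid])
        rec(group[mid:])

    group = sorted(strains)
    if group:
        mid = len(group) // 2
        if len(group) == 1:
            branches.append((group[0], group))
        else:
            rec(group[:mid])
            rec(group[mid:])
    return branches


def simulate_manifest(config: SimConfig) -> tuple[Manifest, TruthTables]:
    """Generate a probe manifest with the configured category counts.

    SNP probes carry strain genotypes following the branch logic of a
    balanced phylogeny (all descendant strains of a branch share its
    alternate alleles); channel-switch probes carry the species whose
    template reads in the channel opposite the design channel.
    """
    if config.n_cg_i_red + config.n_cg_i_grn == 0:
        raise SynthError("need Infinium-I probes (out-of-band background is impossible)")
    rng = config.rng()
    rows = []
    counter = 1
    pos = {}

    def next_coord():
        chrom = f"chr{(len(rows) % 19) + 1}"
        pos[chrom] = pos.get(chrom, 0) + 1000
        return chrom, pos[chrom]

    def add(prefix, chemistry, channel, target, categories="", mask_default=False,
            chrom=None, position=None, extra=None):
        nonlocal counter
        chem_digit = "1" if chemistry == "Infinium-I" else "2"
        strand = rng.choice(["T", "B"]) + rng.choice(["C", "O"])
        pid = f"{prefix}{counter:08d}_{strand}{chem_digit}1"
        counter += 1
        if chrom is None and target != "control":
            chrom, position = next_coord()
        row = {
            "probe_id": pid, "chemistry": chemistry, "channel": channel,
            "target": target, "chrom": chrom, "pos": position,
            "strand": rng.choice(["+", "-"]), "categories": categories,
            "mask_default": mask_default,
        }
        if extra:
            row.update(extra)
        rows.append(row)
        return pid

    for _ in range(config.n_cg_i_red):
        add("cg", "Infinium-I", "Red", "CG", categories="nonsyntenic")
    for _ in range(config.n_cg_i_grn):
        add("cg", "Infinium-I", "Green", "CG", categories="nonsyntenic")
    for _ in range(config.n_cg_ii):
        add("cg", "Infinium-II", "Both", "CG", categories="nonsyntenic")
    for _ in range(config.n_ch):
        add("ch", "Infinium-II", "Both", "CH", categories="nonsyntenic")
    for _ in range(config.n_uk):
        add("uk", "Infinium-II", "Both", "CG", mask_default=True)
    for _ in range(config.n_channel_switch):
        ch = rng.choice(["Red", "Green"])
        add("cg", "Infinium-I", ch, "CG", categories="channel_switch",
            extra={"snp_alt_channel_species": rng.choice(["Human", "Mouse"]),
                   "human_syntenic_id": f"hs{counter:08d}"})
    for _ in range(config.n_control):
        add("ctl", "Infinium-II", "Both", "control")

    genotypes = None
    if config.strains:
        branches = _strain_branches(list(config.strains))
        snp_ids = []
        geno_rows = {s: [] for s in config.strains}
        for _, clade in branches:
            for _ in range(config.snps_per_branch):
                ch = rng.choice(["Red", "Green"])
                pid = add("rs", "Infinium-I", ch, "SNP")
                snp_ids.append(pid)
                for s in config.strains:
                    geno_rows[s].append(1.0 if s in clade else 0.0)
        genotypes = pd.DataFrame(geno_rows, index=snp_ids).T
        df = pd.DataFrame(rows)
        for s in config.strains:
            df[f"genotype_{s}"] = np.nan
            df.loc[df["probe_id"].isin(snp_ids), f"genotype_{s}"] = (
                genotypes.loc[s].reindex(df.loc[df["probe_id"].isin(snp_ids), "probe_id"]).to_numpy()
            )
    else:
        df = pd.DataFrame(rows)

    manifest = Manifest(df)
    return manifest, TruthTables(genotypes=genotypes)


# ---------------------------------------------------------------------------
# Sample sheet & methylomes
# ---------------------------------------------------------------------------

def simulate_sample_sheet(config: SimConfig) -> pd.DataFrame:
    """Sample annotation: tissue, strain, sex, age (months), tumor flag,
    compartment (testis samples form their own compartment)."""
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    strains = list(config.strains) or ["C57BL6"]
    i = 0
    for tissue in config.tissues:
        for _ in range(config.n_per_tissue):
            i += 1
            rows.append({
                "sample": f"S{i:03d}",
                "tissue": tissue,
                "strain": strains[i % len(strains)],
                "sex": "F" if i % 2 else "M",
                "age": float(rng.uniform(*config.age_range_months)),
                "tumor": False,
                "compartment": "testis" if tissue == "testis" else "somatic",
            })
    return pd.DataFrame(rows).set_index("sample")


def simulate_methylomes(
    manifest: Manifest,
    annot: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """True β matrix (probes x samples) plus the per-probe role table.

    Baselines are a low/intermediate/high mixture; designated tissue
    markers shift by the configured delta in their tissue; age probes
    drift linearly (clipped to [0, 1]); imprint-flagged probes sit at 0.5
    in somatic samples and polarize in testis; SNP probes take the
    sample strain's allele fraction so genotyping is exercised end to
    end.
    """
    rng = np.random.default_rng(config.seed + 2)
    man = manifest.df
    cg = man.index[(man["target"].isin(["CG", "CH"])) &
                   (~manifest.has_category("channel_switch"))]
    n = len(cg)
    kind = rng.choice(["low", "mid", "high"], size=n, p=[0.45, 0.1, 0.45])
    baseline = np.where(
        kind == "low", rng.uniform(0.02, 0.15, n),
        np.where(kind == "mid", rng.uniform(0.35, 0.65, n), rng.uniform(0.85, 0.98, n)),
    )
    roles = pd.DataFrame(
        {"baseline": baseline, "marker_tissue": None, "marker_direction": 0,
         "age_slope": 0.0, "is_imprint": False},
        index=cg,
    )
    free = list(cg)
    rng.shuffle(free)
    tissues = [t for t in annot["tissue"].unique() if t != "testis"]
    k = 0
    for tissue in tissues:
        for direction in (1, -1):
            take = free[k:k + config.n_tissue_markers]
            k += config.n_tissue_markers
            roles.loc[take, "marker_tissue"] = tissue
            roles.loc[take, "marker_direction"] = direction
            roles.loc[take, "baseline"] = rng.uniform(
                0.05, 0.25, len(take)) if direction > 0 else rng.uniform(0.75, 0.95, len(take))
    age_take = free[k:k + config.n_age_probes]
    k += config.n_age_probes
    roles.loc[age_take, "age_slope"] = rng.choice([-1, 1], len(age_take)) * config.age_slope
    roles.loc[age_take, "baseline"] = rng.uniform(0.3, 0.6, len(age_take))
    imp_take = free[k:k + config.n_imprint_probes]
    roles.loc[imp_take, "is_imprint"] = True

    betas = pd.DataFrame(index=man.index, columns=annot.index, dtype=float)
    imp_polarity = pd.Series(rng.choice([0.0, 1.0], len(imp_take)), index=imp_take)
    for sample, a in annot.iterrows():
        b = pd.Series(roles["baseline"].to_numpy(copy=True), index=cg)
        markers = roles["marker_tissue"] == a["tissue"]
        b[markers] = b[markers] + roles.loc[markers, "marker_direction"] * config.tissue_delta
        b[age_take] = roles.loc[age_take, "baseline"] + roles.loc[age_take, "age_slope"] * a["age"]
        if a.get("compartment", "somatic") == "testis":
            b[imp_take] = imp_polarity
        else:
            b[imp_take] = 0.5
        noise = rng.normal(0.0, config.beta_noise_sd, len(b))
        betas.loc[cg, sample] = np.clip(b + noise, 0.0, 1.0)
    # SNP probes: allele fraction of the sample's strain
    snp = man.index[man["target"] == "SNP"]
    if len(snp) and "strain" in annot.columns and manifest.strain_names:
        G = manifest.strain_genotypes()
        for sample, a in annot.iterrows():
            if a["strain"] in G.index:
                g = G.loc[a["strain"]].reindex(snp).fillna(0.0)
                betas.loc[snp, sample] = np.clip(
                    g + rng.normal(0.0, config.beta_noise_sd, len(snp)), 0.0, 1.0
                )
    # channel-switch & controls stay at 0.5 (their signal is species- not
    # methylation-driven)
    betas = betas.fillna(0.5)
    return betas, roles


# ---------------------------------------------------------------------------
# Signals
# ---------------------------------------------------------------------------

def _background(rng, config: SimConfig, size) -> np.ndarray:
    return np.maximum(rng.normal(config.bg_mean, config.bg_sd, size), 0.0)


def simulate_signals(
    true_betas: pd.DataFrame,
    manifest: Manifest,
    config: SimConfig,
    seed: int | None = None,
    human_fraction: float = 0.0,
) -> dict:
    """Two-channel allele intensities per sample.

    Each probe's total signal is Exponential(signal_mean) scaled by gain
    and split between alleles by the true β; backgrounds are
    truncated-normal; Red-channel values are multiplied by the dye
    factor; out-of-band slots receive background-only draws.
    Channel-switch probes split their signal between the human and mouse
    channels by ``human_fraction`` instead; non-syntenic probes scale
    with the mouse fraction when a mixture is simulated.
    """
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    man = manifest.df.loc[true_betas.index.intersection(manifest.df.index)]
    switch = manifest.has_category("channel_switch").reindex(man.index, fill_value=False)
    nonsyn = manifest.has_category("nonsyntenic").reindex(man.index, fill_value=False)
    out = {}
    for sample in true_betas.columns:
        beta = true_betas.loc[man.index, sample].to_numpy(dtype=float)
        S = rng.exponential(config.signal_mean, len(man)) * config.gain
        scale = np.where(nonsyn & (human_fraction > 0), 1.0 - human_fraction, 1.0)
        S = S * scale
        sig = pd.DataFrame(
            {c: _background(rng, config, len(man)) for c in ["MG", "UG", "MR", "UR"]},
            index=man.index,
        )
        grn = ((man["chemistry"] == "Infinium-I") & (man["channel"] == "Green")).to_numpy()
        red = ((man["chemistry"] == "Infinium-I") & (man["channel"] == "Red")).to_numpy()
        two = (man["chemistry"] == "Infinium-II").to_numpy()
        sw = switch.to_numpy()
        plain_grn, plain_red = grn & ~sw, red & ~sw
        sig.loc[plain_grn, "MG"] += beta[plain_grn] * S[plain_grn]
        sig.loc[plain_grn, "UG"] += (1 - beta[plain_grn]) * S[plain_grn]
        sig.loc[plain_red, "MR"] += beta[plain_red] * S[plain_red]
        sig.loc[plain_red, "UR"] += (1 - beta[plain_red]) * S[plain_red]
        sig.loc[two, "MG"] += beta[two] * S[two]
        sig.loc[two, "UR"] += (1 - beta[two]) * S[two]
        if sw.any():
            sub = man.loc[sw]
            design_green = (sub["channel"] == "Green").to_numpy()
            alt_human = (sub["snp_alt_channel_species"] == "Human").to_numpy()
            human_green = (design_green & ~alt_human) | (~design_green & alt_human)
            Ssw = S[sw]
            hsig = human_fraction * Ssw
            msig = (1 - human_fraction) * Ssw
            green_sig = np.where(human_green, hsig, msig)
            red_sig = np.where(human_green, msig, hsig)
            sig.loc[sw, "MG"] += green_sig
            sig.loc[sw, "MR"] += red_sig
        sig[["MR", "UR"]] *= config.dye_factor
        out[sample] = SignalFrame(sig)
    return out


def simulate_low_input(
    true_betas: pd.DataFrame | pd.Series,
    n_molecules: int,
    seed: int = 0,
) -> pd.DataFrame | pd.Series:
    """Low-input binomial dropout: each measured β is resampled as
    Binomial(n_molecules, β)/n_molecules, collapsing intermediate values
    toward the extremes as the number of template molecules shrinks."""
    if n_molecules < 1:
        raise SynthError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    vals = np.asarray(true_betas, dtype=float)
    k = rng.binomial(n_molecules, np.clip(vals, 0.0, 1.0))
    out = k / n_molecules
    if isinstance(true_betas, pd.Series):
        return pd.Series(out, index=true_betas.index, name=true_betas.name)
    return pd.DataFrame(out, index=true_betas.index, columns=true_betas.columns)


def simulate_titration(
    meth_source: pd.Series,
    unmeth_source: pd.Series,
    fractions=None,
) -> pd.DataFrame:
    """Molecule-level titration mixing: β_mix = w β_meth + (1-w) β_unmeth
    at each mixing fraction (defaults to the 11-point calibration
    design). Columns are labelled by the fraction."""
    from .mixtures import TITRATION_FRACTIONS

    if fractions is None:
        fractions = TITRATION_FRACTIONS
    fractions = list(fractions)
    if any(w < 0 or w > 1 for w in fractions):
        raise SynthError("titration fractions must lie in [0, 1]")
    cols = {}
    for w in fractions:
        cols[f"w{w:g}"] = w * meth_source + (1 - w) * unmeth_source
    out = pd.DataFrame(cols)
    out.attrs["fractions"] = fractions
    return out


def simulate_species_mixture(
    human_fraction: float,
    config: SimConfig,
    seed: int = 0,
):
    """Paired mouse-array and human-array signal frames for one
    human/mouse DNA mixture sample.

    The mouse array view carries channel-switch probes splitting signal
    between the species' channels and non-syntenic mouse probes scaling
    with (1 - human fraction); the human-array view holds non-syntenic
    human probes scaling with the human fraction.
    """
    if not 0.0 <= human_fraction <= 1.0:
        raise SynthError("human_fraction must lie in [0, 1]")
    m_manifest, _ = simulate_manifest(config)
    rng = np.random.default_rng(seed)
    betas = pd.DataFrame(0.5, index=m_manifest.df.index, columns=["mix"])
    mouse_signals = simulate_signals(
        betas, m_manifest, config, seed=seed + 10, human_fraction=human_fraction
    )["mix"]

    # human-array view: Infinium-II non-syntenic probes scaling with f
    n_h = config.n_cg_ii
    h_rows = pd.DataFrame({
        "probe_id": [f"cg{i:08d}_TC21" for i in range(1, n_h + 1)],
        "chemistry": "Infinium-II", "channel": "Both", "target": "CG",
        "chrom": "chr1", "pos": np.arange(1, n_h + 1) * 1000, "strand": "+",
        "categories": "nonsyntenic", "mask_default": False,
    })
    # a pinch of Infinium-I probes so the human view can also be processed
    n_i = 40
    h_rows_i = pd.DataFrame({
        "probe_id": [f"cg{i:08d}_TC11" for i in range(n_h + 1, n_h + n_i + 1)],
        "chemistry": "Infinium-I",
        "channel": ["Red", "Green"] * (n_i // 2),
        "target": "CG", "chrom": "chr2", "pos": np.arange(1, n_i + 1) * 1000,
        "strand": "+", "categories": "", "mask_default": False,
    })
    h_manifest = Manifest(pd.concat([h_rows, h_rows_i], ignore_index=True))
    h_betas = pd.DataFrame(0.5, index=h_manifest.df.index, columns=["mix"])
    # on the human array, human DNA is the on-target species
    h_config = replace(config, seed=seed + 20)
    h_signals = simulate_signals(
        h_betas, h_manifest, h_config, seed=seed + 20,
        human_fraction=1.0 - human_fraction,
    )["mix"]
    return mouse_signals, h_signals, m_manifest, h_manifest


def simulate_backcross(
    generations: int,
    n_snps: int = 200,
    seed: int = 0,
    tau: float = 0.0,
) -> dict:
    """VAF vectors (donor-allele fraction per SNP) along a backcross.

    Returns a dict with keys ``donor`` (all 1), ``F1`` (all 0.5) and
    ``BC1``..``BCn``; in each backcross to the recipient every
    heterozygous SNP independently stays heterozygous with probability
    1/2 and otherwise becomes recipient-homozygous (linkage is ignored).
    Optional Gaussian noise of s.d. ``tau`` is added, clipped to [0, 1].
    """
    if generations < 0:
        raise SynthError("generations must be >= 0")
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"rs{i:08d}_TC11" for i in range(1, n_snps + 1)], name="snp")
    out = {"donor": pd.Series(1.0, index=idx), "F1": pd.Series(0.5, index=idx)}
    state = np.full(n_snps, 0.5)
    for gen in range(1, generations + 1):
        het = state == 0.5
        stays = rng.random(n_snps) < 0.5
        state = np.where(het & stays, 0.5, np.where(het, 0.0, state))
        out[f"BC{gen}"] = pd.Series(state.copy(), index=idx)
    if tau > 0:
        for key, v in out.items():
            out[key] = pd.Series(
                np.clip(v.to_numpy() + rng.normal(0, tau, n_snps), 0, 1), index=idx
            )
    return out


def simulate_strain_vafs(
    ref: StrainReference,
    strain: str,
    tau: float = 0.05,
    seed: int = 0,
    mixture_with: str | None = None,
    pi: float = 1.0,
) -> pd.Series:
    """Observed VAFs for a pure strain or a two-strain mixture: expected
    allele fractions pi*g_strain + (1-pi)*g_other plus clipped Gaussian
    noise of s.d. tau."""
    rng = np.random.default_rng(seed)
    g = ref.genotypes.loc[strain].astype(float)
    if mixture_with is not None:
        g = pi * g + (1 - pi) * ref.genotypes.loc[mixture_with].astype(float)
    noisy = np.clip(g.to_numpy() + rng.normal(0.0, tau, len(g)), 0.0, 1.0)
    return pd.Series(noisy, index=ref.snps, name="vaf")


def simulate_study(config: SimConfig):
    """Full simulated study: manifest, sample sheet, true β matrix,
    per-sample signal frames and the combined truth tables."""
    manifest, truth = simulate_manifest(config)
    annot = simulate_sample_sheet(config)
    true_betas, roles = simulate_methylomes(manifest, annot, config)
    signals = simulate_signals(true_betas, manifest, config)
    truth.true_betas = true_betas
    truth.probe_roles = roles
    truth.annot = annot
    return manifest, annot, true_betas, signals, truth
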