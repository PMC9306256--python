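"""Probe manifest data model, probe-ID grammar, designability filtering
and genomic-region I/O.

The array's probe IDs carry a four-letter suffix encoding which strand of
the 122-mer template the probe was designed against (T/B), whether it
targets the bisulfite-converted strand or its synthesized opposite (C/O),
the Infinium chemistry (1 = two-bead single-channel, 2 = single-bead
two-channel), and a replicate counter for redundant designs, e.g.
``cg47072751_BC21``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PROBE_PREFIXES = ("cg", "ch", "rs", "uk", "ctl")

_SUFFIX_RE = re.compile(r"^([TB])([CO])([12])([0-9]+)$")


class ProbeIdError(ValueError):
    """Raised when a probe ID does not conform to the ID grammar."""


class ManifestError(ValueError):
    """Raised on malformed manifest or region input."""


@dataclass(frozen=True)
class ProbeIdParts:
    """Decomposed probe ID.

    Attributes
    ----------
    prefix : str
        Probe class tag: ``cg`` (CpG), ``ch`` (non-CpG cytosine), ``rs``
        (SNP), ``uk`` (unknown/multi-mapping, masked by default), ``ctl``
        (control).
    stem : str
        Locus identifier (kept as a string to preserve zero padding).
    template_strand : str
        ``T`` or ``B`` — top or bottom strand of the 122-mer template.
    probe_strand : str
        ``C`` or ``O`` — converted strand or its (opposite) daughter.
    chemistry : int
        1 (Infinium-I) or 2 (Infinium-II).
    replicate : int
        Replicate counter, >= 1.
    """

    prefix: str
    stem: str
    template_strand: str
    probe_strand: str
    chemistry: int
    replicate: int

    def __post_init__(self) -> None:
        if self.prefix not in PROBE_PREFIXES:
            raise ProbeIdError(f"unknown probe prefix {self.prefix!r}")
        if self.template_strand not in ("T", "B"):
            raise ProbeIdError(
                f"template strand must be T or B, got {self.template_strand!r}"
            )
        if self.probe_strand not in ("C", "O"):
            raise ProbeIdError(
                f"probe strand must be C or O, got {self.probe_strand!r}"
            )
        if self.chemistry not in (1, 2):
            raise ProbeIdError(f"chemistry must be 1 or 2, got {self.chemistry!r}")
        if self.replicate < 1:
            raise ProbeIdError(f"replicate must be >= 1, got {self.replicate!r}")

    def format(self) -> str:
        """Format back to a probe ID; inverse of :func:`parse_probe_id`."""
        return (
            f"{self.prefix}{self.stem}_{self.template_strand}"
            f"{self.probe_strand}{self.chemistry}{self.replicate}"
        )


def parse_probe_id(probe_id: str) -> ProbeIdParts:
    """Parse a probe ID into its parts.

    The grammar is ``<prefix><stem>_[TB][CO][12][0-9]+`` where prefix is one
    of cg/ch/rs/uk/ctl.

    Raises
    ------
    ProbeIdError
        Naming the offending token when the ID is malformed.
    """
    if not probe_id:
        raise ProbeIdError("empty probe ID")
    prefix = next((p for p in PROBE_PREFIXES if probe_id.startswith(p)), None)
    if prefix is None:
        raise ProbeIdError(f"unknown prefix in probe ID {probe_id!r}")
    rest = probe_id[len(prefix):]
    stem, sep, suffix = rest.rpartition("_")
    if not sep:
        raise ProbeIdError(f"probe ID {probe_id!r} lacks a '_' suffix separator")
    if not stem:
        raise ProbeIdError(f"probe ID {probe_id!r} has an empty stem")
    m = _SUFFIX_RE.match(suffix)
    if m is None:
        raise ProbeIdError(
            f"malformed suffix {suffix!r} in probe ID {probe_id!r}; "
            "expected [TB][CO][12] followed by a replicate number"
        )
    replicate = int(m.group(4))
    if replicate < 1 or (m.group(4) != str(replicate)):
        raise ProbeIdError(
            f"replicate token {m.group(4)!r} in {probe_id!r} must be a "
            "positive integer without leading zeros"
        )
    return ProbeIdParts(
        prefix=prefix,
        stem=stem,
        template_strand=m.group(1),
        probe_strand=m.group(2),
        chemistry=int(m.group(3)),
        replicate=replicate,
    )


# ---------------------------------------------------------------------------
# Designability filtering
# ---------------------------------------------------------------------------

MAPQ_LENGTHS = (30, 35, 40, "full")
ALLELES = ("M", "U")


@dataclass(frozen=True)
class CandidateDesign:
    """A candidate probe design with the quantities the designability
    filter inspects.

    ``mapq_by_len`` maps (subsequence length, allele) -> mapping quality,
    for lengths 30/35/40/"full" and the methylated (M) / unmethylated (U)
    allele probe sequences. Distances are nucleotides from the probe's
    3'-end; ``cpg_count`` counts CpGs in the entire probe sequence
    (including the interrogated one); ``design_score`` is a 0-1 ranged
    hybridization-efficiency score supplied by the design pipeline.
    """

    mapq_by_len: Mapping[tuple, float]
    dist_snp_3p: float
    dist_cpg_3p: float
    cpg_count: int
    design_score: float

    def __post_init__(self) -> None:
        missing = [
            (ln, al)
            for ln in MAPQ_LENGTHS
            for al in ALLELES
            if (ln, al) not in self.mapq_by_len
        ]
        if missing:
            raise ManifestError(f"mapq_by_len missing entries: {missing}")
        if self.dist_snp_3p < 0 or self.dist_cpg_3p < 0:
            raise ManifestError("3'-end distances must be >= 0")
        if not 0.0 <= self.design_score <= 1.0:
            raise ManifestError("design_score must lie in [0, 1]")


#: Filter thresholds: mapping quality must exceed MAPQ_MIN at every
#: subsequence length for both alleles; no SNP and no off-target CpG within
#: DIST_MIN nt of the 3'-end; fewer than CPG_MAX CpGs in the probe; design
#: score strictly above SCORE_MIN.
MAPQ_MIN = 20
DIST_MIN = 10
CPG_MAX = 6
SCORE_MIN = 0.3


def filter_designable(design: CandidateDesign) -> tuple[bool, list[str]]:
    """Apply the designability filter to one candidate design.

    Returns ``(passes, failed_rules)`` where ``failed_rules`` names each
    violated rule: ``mapq``, ``dist_snp_3p``, ``dist_cpg_3p``, ``cpg_count``,
    ``design_score``. All inequalities are strict: mapq > 20 at all four
    lengths for both alleles, distances > 10 nt, cpg_count < 6, score > 0.3.
    """
    failed: list[str] = []
    if any(q <= MAPQ_MIN for q in design.mapq_by_len.values()):
        failed.append("mapq")
    if design.dist_snp_3p <= DIST_MIN:
        failed.append("dist_snp_3p")
    if design.dist_cpg_3p <= DIST_MIN:
        failed.append("dist_cpg_3p")
    if design.cpg_count >= CPG_MAX:
        failed.append("cpg_count")
    if design.design_score <= SCORE_MIN:
        failed.append("design_score")
    return (not failed, failed)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "probe_id",
    "chemistry",
    "channel",
    "target",
    "chrom",
    "pos",
    "strand",
    "categories",
    "mask_default",
    "human_syntenic_id",
    "snp_ref_allele",
    "snp_alt_allele",
    "snp_alt_channel_species",
]

CHEMISTRIES = ("Infinium-I", "Infinium-II")
CHANNELS = ("Red", "Green", "Both")
TARGETS = ("CG", "CH", "SNP", "control")


class Manifest:
    """Typed probe manifest backed by a DataFrame indexed by probe_id.

    Manifest positions are 1-based (array-annotation convention); BED I/O
    converts at the boundary. Strain genotype columns are named
    ``genotype_<strain>`` with values 0 (reference homozygous),
    1 (alternate homozygous) or NA.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if "probe_id" in df.columns:
            if df["probe_id"].duplicated().any():
                dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
                raise ManifestError(f"duplicate probe_id {dup!r} in manifest")
            df = df.set_index("probe_id")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ManifestError(f"duplicate probe_id {dup!r} in manifest")
        for col in MANIFEST_COLUMNS[1:]:
            if col not in df.columns:
                df[col] = pd.NA
        bad_chem = ~df["chemistry"].isin(CHEMISTRIES)
        if bad_chem.any():
            raise ManifestError(
                f"invalid chemistry for probe {df.index[bad_chem][0]!r}"
            )
        is_one = df["chemistry"] == "Infinium-I"
        if (~df.loc[is_one, "channel"].isin(["Red", "Green"])).any():
            raise ManifestError("Infinium-I probes must have channel Red or Green")
        if (df.loc[~is_one, "channel"] != "Both").any():
            raise ManifestError("Infinium-II probes must have channel Both")
        df["mask_default"] = (
            df["mask_default"].apply(lambda v: bool(v) if pd.notna(v) else False)
        )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    def is_type_i(self) -> pd.Series:
        return self.df["chemistry"] == "Infinium-I"

    def type_i_ids(self, channel: str) -> pd.Index:
        sel = (self.df["chemistry"] == "Infinium-I") & (self.df["channel"] == channel)
        return self.df.index[sel]

    def has_category(self, tag: str) -> pd.Series:
        cats = self.df["categories"].fillna("")
        return cats.str.split(";").apply(lambda xs: tag in xs)

    @property
    def strain_names(self) -> list[str]:
        return [c[len("genotype_"):] for c in self.df.columns if c.startswith("genotype_")]

    def strain_genotypes(self) -> pd.DataFrame:
        """Genotype matrix (strains x SNP probes) from genotype_ columns."""
        cols = [c for c in self.df.columns if c.startswith("genotype_")]
        snp = self.df.index[self.df["target"] == "SNP"]
        g = self.df.loc[snp, cols].T.astype(float)
        g.index = [c[len("genotype_"):] for c in cols]
        return g

    def to_tsv(self, path) -> None:
        self.df.reset_index().rename(columns={"index": "probe_id"}).to_csv(
            path, sep="\t", index=False
        )


def load_manifest(path) -> Manifest:
    """Load a manifest TSV, enforcing the Manifest invariants."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    if "probe_id" not in df.columns:
        raise ManifestError(f"{path}: missing probe_id column")
    if "pos" in df.columns:
        bad = df["pos"].notna() & (pd.to_numeric(df["pos"], errors="coerce") < 1)
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +header +1-based
            raise ManifestError(f"{path}:{line}: manifest positions are 1-based (pos >= 1)")
    return Manifest(df)


# ---------------------------------------------------------------------------
# Region sets
# ---------------------------------------------------------------------------

@dataclass
class RegionSet:
    """A named set of genomic intervals, 0-based half-open."""

    name: str
    intervals: list = field(default_factory=list)  # (chrom, start, end)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ManifestError(
                    f"region {chrom}:{start}-{end} in {self.name!r}: start must be < end"
                )
        self._index: dict | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def sorted(self) -> "RegionSet":
        return RegionSet(self.name, sorted(self.intervals))

    def merged(self) -> "RegionSet":
        """Merge overlapping/adjacent intervals per chromosome."""
        out: list = []
        for chrom, start, end in sorted(self.intervals):
            if out and out[-1][0] == chrom and start <= out[-1][2]:
                out[-1] = (chrom, out[-1][1], max(out[-1][2], end))
            else:
                out.append((chrom, start, end))
        return RegionSet(self.name, out)

    def _build_index(self) -> dict:
        if self._index is None:
            idx: dict = {}
            for chrom, start, end in self.merged().intervals:
                idx.setdefault(chrom, ([], []))
                idx[chrom][0].append(start)
                idx[chrom][1].append(end)
            self._index = {
                c: (np.asarray(s), np.asarray(e)) for c, (s, e) in idx.items()
            }
        return self._index

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) overlaps any interval on chrom."""
        idx = self._build_index()
        if chrom not in idx:
            return False
        starts, ends = idx[chrom]
        # candidate: last merged interval starting before `end`
        i = int(np.searchsorted(starts, end, side="left")) - 1
        return i >= 0 and ends[i] > start

    def overlaps_many(self, chroms: Sequence[str], starts, ends) -> np.ndarray:
        return np.fromiter(
            (self.overlaps(c, s, e) for c, s, e in zip(chroms, starts, ends)),
            dtype=bool,
            count=len(chroms),
        )


def load_regions(path, name: str | None = None) -> RegionSet:
    """Load a BED3(+) file as a RegionSet (0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ManifestError(f"{path}:{lineno}: BED line needs >= 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ManifestError(f"{path}:{lineno}: malformed coordinate") from exc
            if start >= end:
                raise ManifestError(f"{path}:{lineno}: start must be < end")
            intervals.append((fields[0], start, end))
    import os

    return RegionSet(name or os.path.basename(str(path)), intervals)


def write_regions(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
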