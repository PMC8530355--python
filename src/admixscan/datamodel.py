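"""Core domain types and table IO for ancestry-frequency analyses.

The central object is :class:`AncestryMatrix`: a loci x populations matrix of
introgressed-ancestry frequencies with genomic coordinates (bp and cM).  All
genome scans consume it.  Interval sets (genes, peaks, deserts, tracts) use
BED conventions: 0-based half-open coordinates.  Locus tables use 1-based bp
positions (VCF-style); the two conventions never mix silently because
intervals and loci live in different types.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ANCESTRIES = ("maize", "mexicana", "parviglumis")

#: The 6 unordered diploid ancestry-pair states, in canonical order.
DIPLOID_STATES = (
    "maize/maize",
    "mexicana/mexicana",
    "parviglumis/parviglumis",
    "maize/mexicana",
    "maize/parviglumis",
    "mexicana/parviglumis",
)

HOM_STATE = {a: f"{a}/{a}" for a in ANCESTRIES}


class DataValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


@dataclass(frozen=True)
class PopulationSample:
    """One sampled population: a maize field or wild teosinte stand.

    Parameters
    ----------
    pop_id : str
        Unique population label.
    taxon : str
        One of ``maize``, ``mexicana``, ``parviglumis``, ``outgroup``.
    elevation_km : float
        Sampling elevation in kilometres (must be > 0 for sympatric pops).
    n_individuals : int
        Number of sequenced individuals.
    role : str
        ``sympatric`` (member of a paired admixed sample) or ``reference``.
    """

    pop_id: str
    taxon: str
    elevation_km: float
    n_individuals: int = 0
    role: str = "sympatric"

    def __post_init__(self) -> None:
        if self.taxon not in ANCESTRIES + ("outgroup",):
            raise DataValidationError(f"unknown taxon {self.taxon!r}")
        if self.role == "sympatric" and not self.elevation_km > 0:
            raise DataValidationError(
                f"sympatric population {self.pop_id!r} needs elevation_km > 0"
            )


@dataclass
class AncestryMatrix:
    """Loci x populations matrix of introgressed-ancestry frequencies.

    Attributes
    ----------
    loci : pandas.DataFrame
        Columns ``chrom`` (str), ``pos_bp`` (int, 1-based), ``pos_cM`` (float),
        sorted by (chrom, pos_bp), no duplicate positions.
    freqs : pandas.DataFrame
        One column per population; values in [0, 1]; rows align with ``loci``.
    ancestry_label : str
        Which ancestry the frequencies measure (e.g. ``mexicana`` introgressed
        into sympatric maize).
    meta : dict
        Free-form provenance (seed, truncated_fraction, ...).
    """

    loci: pd.DataFrame
    freqs: pd.DataFrame
    ancestry_label: str = "mexicana"
    meta: dict = field(default_factory=dict)

    @property
    def populations(self) -> list[str]:
        return list(self.freqs.columns)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def validate(self) -> "AncestryMatrix":
        if len(self.loci) != len(self.freqs):
            raise DataValidationError("loci and freqs row counts differ")
        vals = self.freqs.to_numpy(float)
        bad = np.where((vals < 0) | (vals > 1))
        if bad[0].size:
            r, c = bad[0][0], bad[1][0]
            raise DataValidationError(
                f"frequency {vals[r, c]} out of [0,1] at row {r}, "
                f"population {self.freqs.columns[c]!r}"
            )
        key = self.loci[["chrom", "pos_bp"]]
        if key.duplicated().any():
            row = int(np.nonzero(key.duplicated().to_numpy())[0][0])
            raise DataValidationError(f"duplicate (chrom, pos_bp) at row {row}")
        for chrom, grp in self.loci.groupby("chrom", sort=False):
            pos = grp["pos_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                row = int(grp.index[np.argmax(np.diff(pos) <= 0) + 1])
                raise DataValidationError(
                    f"loci not sorted by pos_bp on {chrom}: first offending row {row}"
                )
        return self


@dataclass
class IntervalSet:
    """A set of genomic intervals, 0-based half-open (BED semantics)."""

    records: pd.DataFrame  # columns: chrom, start_bp, end_bp, name

    COLUMNS = ("chrom", "start_bp", "end_bp", "name")

    @classmethod
    def from_records(
        cls, rows: Iterable[tuple], chrom_lengths: Mapping[str, int] | None = None
    ) -> "IntervalSet":
        df = pd.DataFrame(list(rows), columns=list(cls.COLUMNS))
        return cls(df).validate(chrom_lengths)

    def validate(self, chrom_lengths: Mapping[str, int] | None = None) -> "IntervalSet":
        df = self.records
        if (df["start_bp"] >= df["end_bp"]).any():
            row = int(np.nonzero((df["start_bp"] >= df["end_bp"]).to_numpy())[0][0])
            raise DataValidationError(f"empty/inverted interval at row {row}")
        if chrom_lengths is not None:
            for _, rec in df.iterrows():
                if rec["chrom"] not in chrom_lengths:
                    raise DataValidationError(f"unknown chromosome {rec['chrom']!r}")
                if rec["end_bp"] > chrom_lengths[rec["chrom"]]:
                    raise DataValidationError(
                        f"interval {rec['name']!r} exceeds {rec['chrom']} length"
                    )
        return self

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class DiploidPosterior:
    """Per-individual per-site posteriors over the 6 diploid ancestry states.

    ``table`` columns: ``individual``, ``chrom``, ``pos_bp`` plus one column
    per state in :data:`DIPLOID_STATES`.  Rows are sorted by
    (individual, chrom, pos_bp).  State probabilities are nonnegative and sum
    to 1 per row (tolerance 1e-6).
    """

    table: pd.DataFrame

    def validate(self) -> "DiploidPosterior":
        probs = self.table[list(DIPLOID_STATES)].to_numpy(float)
        if (probs < 0).any():
            raise DataValidationError("negative posterior probability")
        sums = probs.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-6
        if bad.any():
            row = int(np.nonzero(bad)[0][0])
            raise DataValidationError(
                f"posteriors at row {row} sum to {sums[row]}, not 1"
            )
        return self


# ---------------------------------------------------------------------------
# Point estimates and tract calling
# ---------------------------------------------------------------------------

def point_estimate_ancestry(post, focal: str):
    """Posterior-weighted point estimate of ``focal`` ancestry dosage.

    Returns P(hom focal) + 1/2 * sum of P(het states containing focal), the
    expected fraction of an individual's two haplotypes carrying the focal
    ancestry at the site.  Accepts a :class:`DiploidPosterior`, a DataFrame
    with the 6 state columns, or a mapping state -> probability; returns an
    array (or scalar for a single record).
    """
    if focal not in ANCESTRIES:
        raise DataValidationError(f"unknown focal ancestry {focal!r}")
    if isinstance(post, DiploidPosterior):
        df = post.table
    elif isinstance(post, pd.DataFrame):
        df = post
    else:  # mapping for a single record
        df = pd.DataFrame([dict(post)])
    out = df[HOM_STATE[focal]].to_numpy(float).copy()
    for state in DIPLOID_STATES:
        a, b = state.split("/")
        if a != b and focal in (a, b):
            out += 0.5 * df[state].to_numpy(float)
    return float(out[0]) if len(out) == 1 else out


def call_homozygous_tracts(
    post: DiploidPosterior,
    threshold: float = 0.8,
    chrom_lengths: Mapping[str, int] | None = None,
) -> IntervalSet:
    """Call high-confidence homozygous ancestry tracts per individual.

    A site qualifies for ancestry ``a`` when P(hom a) > ``threshold``
    (strict).  Maximal runs of qualifying sites form one tract whose span
    reaches halfway to the flanking non-qualifying (or missing) sites; at
    chromosome ends the tract extends to the chromosome boundary when
    ``chrom_lengths`` is given, otherwise it is clipped at the terminal
    site position.  Sites with missing posteriors split tracts.

    Returns an :class:`IntervalSet` whose records carry extra columns
    ``individual`` and ``ancestry`` (name = ``{individual}:{ancestry}``).
    """
    rows = []
    df = post.table
    for (ind, chrom), grp in df.groupby(["individual", "chrom"], sort=False):
        pos = grp["pos_bp"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise DataValidationError(
                f"sites not sorted for individual {ind!r} on {chrom}"
            )
        n = len(pos)
        # half-open site spans: halfway to each neighbour, 0-based
        left = np.empty(n)
        right = np.empty(n)
        left[1:] = (pos[:-1] + pos[1:]) / 2.0
        right[:-1] = left[1:]
        if chrom_lengths is not None:
            left[0] = 0.0
            right[-1] = float(chrom_lengths[chrom])
        else:
            left[0] = float(pos[0]) - 1.0  # the site's own bp, 0-based
            right[-1] = float(pos[-1])
        for anc in ANCESTRIES:
            p = grp[HOM_STATE[anc]].to_numpy(float)
            qual = (p > threshold) & ~np.isnan(p)
            if not qual.any():
                continue
            # maximal runs of qualifying sites
            edges = np.diff(np.concatenate([[0], qual.view(np.int8), [0]]))
            starts = np.nonzero(edges == 1)[0]
            ends = np.nonzero(edges == -1)[0] - 1
            for s, e in zip(starts, ends):
                rows.append(
                    (
                        chrom,
                        int(np.floor(left[s])),
                        int(np.ceil(right[e])),
                        f"{ind}:{anc}",
                        ind,
                        anc,
                    )
                )
    rec = pd.DataFrame(
        rows, columns=["chrom", "start_bp", "end_bp", "name", "individual", "ancestry"]
    )
    return IntervalSet(rec)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_population_metadata(path) -> list[PopulationSample]:
    """Read population metadata CSV (pop_id, taxon, elevation_km, n_individuals, role)."""
    df = pd.read_csv(path)
    return [
        PopulationSample(
            pop_id=str(r.pop_id),
            taxon=str(r.taxon),
            elevation_km=float(r.elevation_km),
            n_individuals=int(getattr(r, "n_individuals", 0)),
            role=str(getattr(r, "role", "sympatric")),
        )
        for r in df.itertuples(index=False)
    ]


def write_population_metadata(samples: Sequence[PopulationSample], path) -> None:
    pd.DataFrame([vars(s) for s in samples]).to_csv(path, index=False)


def read_ancestry_matrix(
    path, metadata: Sequence[PopulationSample] | None = None, ancestry_label: str = "mexicana"
) -> AncestryMatrix:
    """Read an ancestry-frequency TSV (chrom, pos_bp, pos_cM, one column/pop).

    Validation failures are reported with 1-based file line numbers (header is
    line 1).  If ``metadata`` is given, every frequency column must name a
    known population.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    fixed = ["chrom", "pos_bp", "pos_cM"]
    for col in fixed:
        if col not in df.columns:
            raise DataValidationError(f"missing required column {col!r}")
    pops = [c for c in df.columns if c not in fixed]
    if metadata is not None:
        known = {s.pop_id for s in metadata}
        unknown = [p for p in pops if p not in known]
        if unknown:
            raise DataValidationError(f"unknown population column(s): {unknown}")
    vals = df[pops].to_numpy(float)
    bad = np.where((vals < 0) | (vals > 1) | ~np.isfinite(vals))
    if bad[0].size:
        r, c = int(bad[0][0]), int(bad[1][0])
        raise DataValidationError(
            f"frequency {vals[r, c]} out of [0,1] at line {r + 2}, "
            f"population {pops[c]!r}"
        )
    key = df[["chrom", "pos_bp"]]
    if key.duplicated().any():
        row = int(np.nonzero(key.duplicated().to_numpy())[0][0])
        raise DataValidationError(f"duplicated (chrom, pos) at line {row + 2}")
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos_bp"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            i = int(grp.index[int(np.argmax(np.diff(pos) <= 0)) + 1])
            raise DataValidationError(f"unsorted loci: first offending line {i + 2}")
    return AncestryMatrix(
        loci=df[fixed].copy(), freqs=df[pops].copy(), ancestry_label=ancestry_label
    ).validate()


def write_ancestry_matrix(anc: AncestryMatrix, path) -> None:
    out = pd.concat([anc.loci.reset_index(drop=True), anc.freqs.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_bed(path) -> IntervalSet:
    """Read a BED3+ file into an :class:`IntervalSet` (extra columns ignored)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype={0: str}
    )
    ncol = df.shape[1]
    cols = ["chrom", "start_bp", "end_bp"] + (["name"] if ncol > 3 else [])
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    if "name" not in df.columns:
        df["name"] = [f"iv{i}" for i in range(len(df))]
    return IntervalSet(df[list(IntervalSet.COLUMNS)]).validate()


def write_bed(ivs: IntervalSet, path) -> None:
    ivs.records[list(IntervalSet.COLUMNS)].to_csv(
        path, sep="\t", index=False, header=False
    )


def write_tsv_with_meta(df: pd.DataFrame, path, meta: Mapping[str, object]) -> None:
    """Write a TSV with ``# key=value`` header lines (binary-free persistence)."""
    buf = io.StringIO()
    for k, v in meta.items():
        buf.write(f"# {k}={v}\n")
    df.to_csv(buf, sep="\t", index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_tsv_with_meta(path) -> tuple[pd.DataFrame, dict]:
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = 0
    for line in lines:
        if line.startswith("# ") and "=" in line:
            k, v = line[2:].rstrip("\n").split("=", 1)
            meta[k] = v
            body += 1
        else:
            break
    df = pd.read_csv(io.StringIO("".join(lines[body:])), sep="\t")
    return df, meta
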