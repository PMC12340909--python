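"""Hydrogen-deuterium exchange (HDX-MS) uptake engine.

Converts peptide centroid-mass measurements into back-exchange-normalised
deuteration levels, consolidates them to residue level, and computes
differential exchange maps (pseudo-residue dD-bar) between protein states.

Input tables
------------
Peptide pool : columns ``id, sequence, start, end, charge`` with 1-based
inclusive residue coordinates on the protein.

Centroids : columns ``peptide_id, state, timepoint_s, replicate,
centroid_mass_da`` holding neutral monoisotopic-scale masses.  Two state
sentinels carry the controls: ``UNDEUTERATED`` (reference mass, no
timepoint semantics) and ``FULL_D`` (maximally exchanged control, pooled
across replicates and protein states when normalising).

All deuteration levels are expressed as percent of the per-peptide
maximum uptake.  The maximum comes from the full-D control when present,
otherwise from the theoretical limit ``exchangeable amides x D2O
fraction``.  Values outside [0, 100] are retained (noise is informative
downstream) and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

from .errors import DataFormatError

#: State sentinels in centroid tables.
UNDEUTERATED = "UNDEUTERATED"
FULL_D = "FULL_D"

#: Mass of a proton, Da (for m/z -> neutral mass conversion).
PROTON_MASS = 1.00728

_AA = set("ACDEFGHIKLMNPQRSTVWY")

POOL_COLUMNS = ["id", "sequence", "start", "end", "charge"]
CENTROID_COLUMNS = ["peptide_id", "state", "timepoint_s", "replicate", "centroid_mass_da"]


# ---------------------------------------------------------------------------
# masses and small numeric utilities
# ---------------------------------------------------------------------------

def peptide_monoisotopic_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of a peptide: residue masses plus one water.

    Raises
    ------
    DataFormatError
        If the sequence is empty or contains a non-standard residue letter.
    """
    if not sequence:
        raise DataFormatError("empty peptide sequence")
    bad = set(sequence) - _AA
    if bad:
        raise DataFormatError(f"unknown residue letter(s): {sorted(bad)}")
    return float(_ptmass.calculate_mass(sequence=sequence))


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error in parts per million: 1e6*(obs - theo)/theo."""
    return 1e6 * (observed - theoretical) / theoretical


def mz_to_neutral_mass(mz: float, charge: int) -> float:
    """Convert an observed m/z at a given positive charge to neutral mass."""
    if charge < 1:
        raise DataFormatError(f"charge must be >= 1, got {charge}")
    return charge * mz - charge * PROTON_MASS


# ---------------------------------------------------------------------------
# exchangeable amides
# ---------------------------------------------------------------------------

def exchangeable_amides(sequence: str, exclude_second: bool = False) -> int:
    """Number of backbone amides in a peptide that can retain deuterium.

    The first residue's amide is excluded (it is the free N-terminus after
    digestion) and prolines carry no amide hydrogen.  ``exclude_second``
    additionally drops the second residue, the common fast-back-exchange
    convention.
    """
    return len(exchangeable_positions(sequence, 1, exclude_second=exclude_second))


def exchangeable_positions(sequence: str, start: int, exclude_second: bool = False) -> list[int]:
    """Absolute (1-based) residue positions of exchangeable amides.

    ``start`` is the peptide's first residue position on the protein; the
    counting convention matches :func:`exchangeable_amides`.
    """
    if not sequence:
        raise DataFormatError("empty peptide sequence")
    first_idx = 2 if exclude_second else 1  # 0-based index into sequence
    return [
        start + i
        for i in range(first_idx, len(sequence))
        if sequence[i] != "P"
    ]


# ---------------------------------------------------------------------------
# pool filtering
# ---------------------------------------------------------------------------

def filter_peptide_pool(
    pool: pd.DataFrame,
    observed_masses: dict[str, float] | None = None,
    min_len: int = 3,
    max_len: int = 15,
    max_charge: int = 3,
    ppm_tol: float = 7.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply pool-level quality filters and return (kept, rejection log).

    Filters: peptide length within ``[min_len, max_len]``, charge at most
    ``max_charge``, and, when an observed undeuterated mass is supplied for
    a peptide, absolute ppm error against the theoretical monoisotopic mass
    within ``ppm_tol``.  The rejection log has columns ``id, reason``.
    """
    _require_columns(pool, POOL_COLUMNS, "peptide pool")
    keep = []
    rejected = []
    for row in pool.itertuples(index=False):
        n = len(row.sequence)
        if not (min_len <= n <= max_len):
            rejected.append((row.id, f"length {n} outside [{min_len}, {max_len}]"))
            continue
        if row.charge > max_charge:
            rejected.append((row.id, f"charge {row.charge} above cutoff {max_charge}"))
            continue
        if observed_masses is not None and row.id in observed_masses:
            err = ppm_error(observed_masses[row.id], peptide_monoisotopic_mass(row.sequence))
            if abs(err) > ppm_tol:
                rejected.append((row.id, f"mass error {err:+.1f} ppm beyond {ppm_tol} ppm"))
                continue
        keep.append(row.id)
    kept = pool[pool["id"].isin(keep)].reset_index(drop=True)
    log = pd.DataFrame(rejected, columns=["id", "reason"])
    return kept, log


# ---------------------------------------------------------------------------
# uptake computation and normalisation
# ---------------------------------------------------------------------------

def compute_uptake(centroids: pd.DataFrame, peptide_id: str, state: str, timepoint: float) -> float:
    """Deuterium uptake D (Da) of one peptide in one state at one timepoint.

    D is the replicate-mean centroid mass minus the replicate-mean
    undeuterated centroid mass for the same peptide.
    """
    sub = centroids[centroids["peptide_id"] == peptide_id]
    m0 = _undeuterated_mass(sub, peptide_id)
    sel = sub[(sub["state"] == state) & (sub["timepoint_s"] == timepoint)]
    if sel.empty:
        raise DataFormatError(f"no centroid rows for {peptide_id!r} state {state!r} t={timepoint}")
    return float(sel["centroid_mass_da"].mean() - m0)


def _undeuterated_mass(sub: pd.DataFrame, peptide_id: str) -> float:
    ref = sub[sub["state"] == UNDEUTERATED]
    if ref.empty:
        raise DataFormatError(f"no undeuterated reference for peptide {peptide_id!r}")
    return float(ref["centroid_mass_da"].mean())


def normalize_uptake(
    D: float,
    peptide_sequence: str,
    fulld_uptakes: np.ndarray | None,
    d2o_fraction: float = 0.9,
    exclude_second: bool = False,
) -> tuple[float, float, str]:
    """Express uptake as percent of the per-peptide maximum.

    ``fulld_uptakes`` are full-D control uptakes (centroid minus
    undeuterated mass, Da) pooled across replicates and protein states;
    when absent or empty the theoretical maximum ``exchangeable amides x
    d2o_fraction`` is used.  Returns ``(pct_max, max_D, source)``; raises
    :class:`DataFormatError` when the maximum is not positive.
    """
    if not 0 < d2o_fraction <= 1:
        raise DataFormatError(f"d2o_fraction must be in (0, 1], got {d2o_fraction}")
    if fulld_uptakes is not None and len(fulld_uptakes) > 0:
        max_d = float(np.mean(fulld_uptakes))
        source = "full-D"
    else:
        max_d = exchangeable_amides(peptide_sequence, exclude_second) * d2o_fraction
        source = "theoretical"
    if max_d <= 0:
        raise DataFormatError(f"non-positive maximum uptake ({max_d:g} Da, {source})")
    return 100.0 * D / max_d, max_d, source


def analyze_uptake(
    pool: pd.DataFrame,
    centroids: pd.DataFrame,
    d2o_fraction: float = 0.9,
    exclude_second: bool = False,
) -> pd.DataFrame:
    """Per-peptide uptake table for every (state, timepoint) measurement.

    Columns: ``peptide_id, state, timepoint_s, D, max_D, max_d_source,
    pct_max, out_of_range``.  Peptides without an undeuterated reference
    or with a non-positive maximum are dropped; the reasons are collected
    in ``df.attrs['excluded']``.
    """
    _require_columns(pool, POOL_COLUMNS, "peptide pool")
    _require_columns(centroids, CENTROID_COLUMNS, "centroid table")
    records = []
    excluded: list[tuple[str, str]] = []
    for pep in pool.itertuples(index=False):
        sub = centroids[centroids["peptide_id"] == pep.id]
        try:
            m0 = _undeuterated_mass(sub, pep.id)
        except DataFormatError as exc:
            excluded.append((pep.id, str(exc)))
            continue
        fulld = sub[sub["state"] == FULL_D]["centroid_mass_da"].to_numpy()
        fulld_uptakes = fulld - m0 if len(fulld) else None
        sample = sub[~sub["state"].isin([UNDEUTERATED, FULL_D])]
        grouped = sample.groupby(["state", "timepoint_s"], sort=True)["centroid_mass_da"].mean()
        for (state, t), mean_mass in grouped.items():
            D = float(mean_mass - m0)
            try:
                pct, max_d, source = normalize_uptake(
                    D, pep.sequence, fulld_uptakes, d2o_fraction, exclude_second
                )
            except DataFormatError as exc:
                excluded.append((pep.id, str(exc)))
                break
            records.append(
                (pep.id, state, float(t), D, max_d, source, pct, not 0.0 <= pct <= 100.0)
            )
    out = pd.DataFrame(
        records,
        columns=[
            "peptide_id", "state", "timepoint_s", "D",
            "max_D", "max_d_source", "pct_max", "out_of_range",
        ],
    )
    out.attrs["excluded"] = excluded
    return out


# ---------------------------------------------------------------------------
# residue-level consolidation and differential maps
# ---------------------------------------------------------------------------

def consolidate_residue_levels(
    uptake: pd.DataFrame, pool: pd.DataFrame, protein_length: int
) -> pd.DataFrame:
    """Average peptide %-of-maximum levels onto residues.

    For each state, residue and timepoint, the level is the unweighted mean
    of ``pct_max`` over peptides whose [start, end] span contains the
    residue.  Residues with no covering peptide are absent from the output.
    Columns: ``state, residue, timepoint_s, level, n_covering``.
    """
    _require_columns(pool, POOL_COLUMNS, "peptide pool")
    spans = {row.id: (int(row.start), int(row.end)) for row in pool.itertuples(index=False)}
    bad = [
        pid for pid, (s, e) in spans.items()
        if not (1 <= s <= e <= protein_length)
    ]
    if bad:
        raise DataFormatError(f"peptide span(s) outside [1, {protein_length}]: {bad}")
    rows = []
    for (state, t), grp in uptake.groupby(["state", "timepoint_s"], sort=True):
        acc = np.zeros(protein_length + 1)
        cnt = np.zeros(protein_length + 1, dtype=int)
        for rec in grp.itertuples(index=False):
            s, e = spans[rec.peptide_id]
            acc[s : e + 1] += rec.pct_max
            cnt[s : e + 1] += 1
        covered = np.nonzero(cnt)[0]
        for r in covered:
            rows.append((state, int(r), float(t), acc[r] / cnt[r], int(cnt[r])))
    return pd.DataFrame(rows, columns=["state", "residue", "timepoint_s", "level", "n_covering"])


@dataclass
class ResidueExchangeMap:
    """Residue-level differential exchange between two protein states.

    ``deltas`` is a residue x timepoint matrix of level differences
    (variant minus reference, percentage points); ``dDbar`` is the mean of
    each row over the averaged timepoints; ``n_covering`` counts peptides
    covering each residue in the variant state.
    """

    variant: str
    reference: str
    deltas: pd.DataFrame
    dDbar: pd.Series
    n_covering: pd.Series

    def to_frame(self) -> pd.DataFrame:
        """Woods-plot-ready table: residue, dDbar, n_covering (+per-t deltas)."""
        out = self.deltas.copy()
        out.columns = [f"delta_t{c:g}" for c in out.columns]
        out.insert(0, "dDbar", self.dDbar)
        out["n_covering"] = self.n_covering
        out.index.name = "residue"
        return out.reset_index()


def differential_exchange(
    levels: pd.DataFrame,
    variant: str,
    reference: str,
    include_t0: bool = False,
) -> ResidueExchangeMap:
    """Subtract residue levels between states and average over timepoints.

    Both states must have been measured on the same timepoint grid
    (mismatched grids are an error, not interpolated).  delta(r, t) is
    defined only where both states cover residue r; dDbar(r) averages the
    defined deltas over the timepoints, excluding t = 0 unless
    ``include_t0`` (the zero point carries no exchange information).
    """
    lv = _pivot_state(levels, variant)
    lr = _pivot_state(levels, reference)
    tv, tr = list(lv.columns), list(lr.columns)
    if tv != tr:
        raise DataFormatError(
            f"timepoint grids differ between states: {variant}={tv} vs {reference}={tr}"
        )
    residues = lv.index.union(lr.index)
    deltas = lv.reindex(residues) - lr.reindex(residues)
    avg_cols = [t for t in deltas.columns if include_t0 or t > 0]
    if not avg_cols:
        raise DataFormatError("no timepoints available for dDbar averaging")
    dDbar = deltas[avg_cols].mean(axis=1)
    ncov = (
        levels[levels["state"] == variant]
        .groupby("residue")["n_covering"].max()
        .reindex(residues)
        .fillna(0)
        .astype(int)
    )
    return ResidueExchangeMap(variant, reference, deltas, dDbar, ncov)


def _pivot_state(levels: pd.DataFrame, state: str) -> pd.DataFrame:
    sub = levels[levels["state"] == state]
    if sub.empty:
        raise DataFormatError(f"state {state!r} absent from level table")
    return sub.pivot(index="residue", columns="timepoint_s", values="level").sort_index()


# ---------------------------------------------------------------------------
# coverage summary and segment classification
# ---------------------------------------------------------------------------

@dataclass
class ExchangeSummary:
    """Pool-level coverage statistics.

    coverage: percent of protein residues covered by at least one peptide;
    redundancy: mean number of covering peptides over covered residues
    (NaN for an empty pool); average_peptide_length and peptide_count are
    plain mean/count.
    """

    coverage: float
    redundancy: float
    average_peptide_length: float
    peptide_count: int


def summarize_coverage(pool: pd.DataFrame, protein_length: int) -> ExchangeSummary:
    """Sequence coverage, redundancy and mean peptide length of a pool."""
    _require_columns(pool, POOL_COLUMNS, "peptide pool")
    if protein_length < 1:
        raise DataFormatError(f"protein_length must be >= 1, got {protein_length}")
    cnt = np.zeros(protein_length + 1, dtype=int)
    lengths = []
    for row in pool.itertuples(index=False):
        s, e = int(row.start), int(row.end)
        if not (1 <= s <= e <= protein_length):
            raise DataFormatError(f"peptide {row.id!r} span [{s}, {e}] outside protein")
        cnt[s : e + 1] += 1
        lengths.append(e - s + 1)
    covered = cnt[1:] > 0
    coverage = 100.0 * covered.sum() / protein_length
    redundancy = float(cnt[1:][covered].mean()) if covered.any() else float("nan")
    avg_len = float(np.mean(lengths)) if lengths else float("nan")
    return ExchangeSummary(coverage, redundancy, avg_len, len(lengths))


def classify_exchange_regions(
    dDbar: pd.Series, threshold: float, min_run: int
) -> pd.DataFrame:
    """Segment a dD-bar map into deprotected / protected runs.

    Maximal runs of at least ``min_run`` consecutive residues with dDbar
    >= +threshold are labelled ``deprotected``; runs <= -threshold are
    ``protected``.  Residues missing from the map (or NaN) break runs.
    Returns columns ``start, end, label, mean_dDbar``.
    """
    if threshold <= 0:
        raise DataFormatError(f"threshold must be > 0, got {threshold}")
    if min_run < 1:
        raise DataFormatError(f"min_run must be >= 1, got {min_run}")
    s = dDbar.dropna().sort_index()
    segments = []
    run_start = None
    run_label = None
    prev_res = None

    def flush(end_res):
        if run_start is not None and end_res - run_start + 1 >= min_run:
            vals = s.loc[run_start:end_res]
            segments.append((run_start, end_res, run_label, float(vals.mean())))

    for res, val in s.items():
        label = "deprotected" if val >= threshold else "protected" if val <= -threshold else None
        contiguous = prev_res is not None and res == prev_res + 1
        if label != run_label or not contiguous:
            flush(prev_res)
            run_start = res if label else None
            run_label = label
        prev_res = res
    flush(prev_res)
    return pd.DataFrame(segments, columns=["start", "end", "label", "mean_dDbar"])


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataFormatError(f"{what} missing column(s): {missing}")
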