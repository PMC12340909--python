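"""Phosphosite observation-frequency ranking and hotspot calling.

Works on curated phosphosite dumps in the PhosphoSitePlus TSV dialect
(descriptive preamble, then a tab-separated header with GENE, ACC_ID,
MOD_RSD, ORGANISM, LT_LIT, MS_LIT, MS_CST among other columns;
gzip-transparent).  The observation count of a site is MS_LIT + MS_CST
(literature plus in-house MS studies); its literature-support ratio is
(LT_LIT + 1) / (MS_CST + MS_LIT).  Hotspots are the top ceil(q*N) sites
by observation count (default q = 0.001, i.e. the top 0.1%).

Differential phosphosite tables from tumor-vs-wildtype comparisons are
consumed as given (site id, log2 fold change, significance) and ranked by
absolute fold change among significance-passing rows.
"""

from __future__ import annotations

import gzip
import io
import logging
import math
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataFormatError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["GENE", "ACC_ID", "MOD_RSD", "ORGANISM", "LT_LIT", "MS_LIT", "MS_CST"]
_COUNT_COLUMNS = ["LT_LIT", "MS_LIT", "MS_CST"]

_SITE_RE = re.compile(r"^([A-Za-z])(\d+)(?:-(\w+))?$")


def parse_site_label(label: str) -> tuple[str, int, str | None]:
    """Split a modified-residue label like ``Y62-p`` into (letter, position, suffix)."""
    m = _SITE_RE.match(str(label).strip())
    if not m or int(m.group(2)) < 1:
        raise DataFormatError(f"unparsable site label: {label!r}")
    return m.group(1).upper(), int(m.group(2)), m.group(3)


def _open_maybe_gzip(path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_phosphosite_dataset(
    path: str | Path, organism_filter: str | None = None
) -> pd.DataFrame:
    """Read a curated phosphosite TSV (optionally gzipped) into records.

    Skips any preamble above the header row, keeps rows matching
    ``organism_filter`` (case-insensitive; None keeps all), reads missing
    count cells as 0, and preserves file order.  Rows whose MOD_RSD does
    not parse are skipped with a logged warning; the skip count is stored
    in ``df.attrs['n_skipped']`` and dropped-organism count in
    ``df.attrs['n_organism_dropped']``.  Both the raw row count and the
    count after deduplicating (ACC_ID, MOD_RSD) are recorded in attrs.
    """
    with _open_maybe_gzip(path) as fh:
        lines = fh.read().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        cols = line.split("\t")
        if all(c in cols for c in REQUIRED_COLUMNS):
            header_idx = i
            break
    if header_idx is None:
        # find which required column never appears, for a usable message
        seen = set()
        for line in lines:
            seen.update(line.split("\t"))
        missing = [c for c in REQUIRED_COLUMNS if c not in seen]
        raise DataFormatError(
            f"no header row with required columns; missing {missing or REQUIRED_COLUMNS}"
        )
    df = pd.read_csv(
        io.StringIO("\n".join(lines[header_idx:])), sep="\t", dtype=str
    )
    for col in _COUNT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0).astype(int)

    n_dropped = 0
    if organism_filter is not None:
        keep = df["ORGANISM"].str.lower() == organism_filter.lower()
        n_dropped = int((~keep).sum())
        df = df[keep]

    parsed = []
    n_skipped = 0
    for _, row in df.iterrows():
        try:
            letter, pos, _suffix = parse_site_label(row["MOD_RSD"])
        except DataFormatError:
            n_skipped += 1
            logger.warning("skipping row with unparsable site label %r", row["MOD_RSD"])
            continue
        parsed.append(
            (
                row["GENE"], row["ACC_ID"], row["MOD_RSD"], letter, pos,
                row["ORGANISM"], row["LT_LIT"], row["MS_LIT"], row["MS_CST"],
            )
        )
    out = pd.DataFrame(
        parsed,
        columns=[
            "gene", "protein_acc", "site", "residue", "position",
            "organism", "LT_LIT", "MS_LIT", "MS_CST",
        ],
    )
    out.attrs["n_skipped"] = n_skipped
    out.attrs["n_organism_dropped"] = n_dropped
    out.attrs["n_raw"] = len(out)
    out.attrs["n_dedup"] = int(len(out.drop_duplicates(["protein_acc", "site"])))
    return out


def score_observations(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``observations`` and ``lit_ratio`` columns.

    observations = MS_LIT + MS_CST; lit_ratio = (LT_LIT + 1) / (MS_CST +
    MS_LIT), reported as missing (NaN) when the denominator is zero.
    Negative counts are rejected.
    """
    for col in _COUNT_COLUMNS:
        if col not in records.columns:
            raise DataFormatError(f"records missing count column {col!r}")
        if (records[col] < 0).any():
            raise DataFormatError(f"negative counts in {col}")
    out = records.copy()
    denom = out["MS_LIT"] + out["MS_CST"]
    out["observations"] = denom
    with np.errstate(divide="ignore"):
        out["lit_ratio"] = np.where(denom > 0, (out["LT_LIT"] + 1) / denom, np.nan)
    return out


def call_hotspots(records: pd.DataFrame, q: float = 0.001) -> pd.DataFrame:
    """Rank sites by observation count and flag the top quantile.

    Sites are sorted descending by observations with a stable sort, so
    ties keep file order; the top ``ceil(q * N)`` are flagged as hotspots.
    Returns the scored table with ``rank`` (1-based) and ``is_hotspot``.
    """
    if not 0 < q <= 1:
        raise DataFormatError(f"q must be in (0, 1], got {q}")
    if len(records) == 0:
        raise DataFormatError("empty phosphosite table")
    scored = score_observations(records)
    order = (
        scored["observations"]
        .reset_index(drop=True)
        .sort_values(ascending=False, kind="stable")
        .index
    )
    scored = scored.reset_index(drop=True).iloc[order].reset_index(drop=True)
    scored["rank"] = np.arange(1, len(scored) + 1)
    n_hot = math.ceil(q * len(scored))
    scored["is_hotspot"] = scored["rank"] <= n_hot
    return scored


def summarize_protein_hotspots(hotspot_table: pd.DataFrame) -> pd.DataFrame:
    """Per-protein hotspot-site counts, ranked.

    Groups hotspot rows by protein accession and ranks by hotspot-site
    count (descending), breaking ties by total observations.  Empty when
    no site is flagged.
    """
    hot = hotspot_table[hotspot_table["is_hotspot"]]
    if hot.empty:
        return pd.DataFrame(columns=["protein_acc", "gene", "n_hotspot_sites", "total_observations"])
    grp = (
        hot.groupby("protein_acc", sort=False)
        .agg(
            gene=("gene", "first"),
            n_hotspot_sites=("site", "size"),
            total_observations=("observations", "sum"),
        )
        .reset_index()
    )
    grp = grp.sort_values(
        ["n_hotspot_sites", "total_observations"],
        ascending=[False, False],
        kind="stable",
    ).reset_index(drop=True)
    return grp


def rank_differential_sites(
    table: pd.DataFrame,
    alpha: float,
    direction: str,
    site_col: str = "site",
    lfc_col: str = "log2fc",
    sig_col: str = "pvalue",
    query_site: str | None = None,
    criterion: str = "lfc",
) -> tuple[pd.DataFrame, int | None]:
    """Rank significant differential sites by effect size.

    Keeps rows with significance <= alpha whose log2 fold change matches
    ``direction`` ('up' for positive, 'down' for negative), then ranks
    descending by |log2FC| (``criterion='lfc'``), ascending by
    significance (``'sig'``), or lexicographically by (|log2FC|,
    significance) (``'both'``).  Returns the ranked table and the 1-based
    rank of ``query_site`` (None when absent).
    """
    if not 0 < alpha < 1:
        raise DataFormatError(f"alpha must be in (0, 1), got {alpha}")
    if direction not in ("up", "down"):
        raise DataFormatError(f"unknown direction {direction!r} (use 'up' or 'down')")
    if criterion not in ("lfc", "sig", "both"):
        raise DataFormatError(f"unknown ranking criterion {criterion!r}")
    for col in (site_col, lfc_col, sig_col):
        if col not in table.columns:
            raise DataFormatError(f"differential table missing column {col!r}")
    sig = table[table[sig_col] <= alpha]
    if direction == "up":
        sig = sig[sig[lfc_col] > 0]
    else:
        sig = sig[sig[lfc_col] < 0]
    sig = sig.copy()
    sig["abs_lfc"] = sig[lfc_col].abs()
    if criterion == "lfc":
        sig = sig.sort_values("abs_lfc", ascending=False, kind="stable")
    elif criterion == "sig":
        sig = sig.sort_values(sig_col, ascending=True, kind="stable")
    else:
        sig = sig.sort_values(["abs_lfc", sig_col], ascending=[False, True], kind="stable")
    sig = sig.reset_index(drop=True)
    sig["rank"] = np.arange(1, len(sig) + 1)
    query_rank = None
    if query_site is not None:
        hit = sig[sig[site_col] == query_site]
        if not hit.empty:
            query_rank = int(hit["rank"].iloc[0])
    return sig, query_rank
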