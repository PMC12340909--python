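"""End-to-end orchestration: config validation, stage running, reports.

A run is described by a single YAML or JSON config with per-stage blocks
and executes the requested stages in declared order.  Every run writes a
``manifest.json`` recording input digests, parameters, seed and output
files, so identical (inputs, config, seed) reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import hdx, hotspot, kinetics, simulate, structure
from .errors import ConfigError, DataFormatError

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate_hdx", "hotspot", "hdx", "kinetics", "structure")
_TOP_KEYS = {"stages", "seed", "log_level"} | set(KNOWN_STAGES)


def load_config(path: str | Path) -> dict:
    """Load and validate a run config from YAML or JSON."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return validate_config(cfg, base_dir=Path(path).parent)


def validate_config(cfg: dict, base_dir: Path | None = None) -> dict:
    """Reject unknown keys, check stage blocks and input-path existence."""
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    stages = cfg.get("stages", [])
    for st in stages:
        if st not in KNOWN_STAGES:
            raise ConfigError(f"unknown stage {st!r}; known: {KNOWN_STAGES}")
        if st != "simulate_hdx" and st not in cfg:
            raise ConfigError(f"stage {st!r} requested but has no config block")
    base = base_dir or Path(".")
    generated: set[str] = set()
    if "simulate_hdx" in stages:
        generated.update({"pool.csv", "centroids.csv"})
    for st in stages:
        block = cfg.get(st, {})
        for key, val in block.items():
            if key in ("pool", "centroids", "dataset", "differential", "rates",
                       "melt", "activation", "model", "closed", "open", "reference"):
                p = Path(val)
                candidate = p if p.is_absolute() else base / p
                if p.name in generated:
                    continue  # produced by an earlier stage of this run
                if not candidate.exists():
                    raise ConfigError(f"stage {st!r}: input path does not exist: {val}")
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: dict, outdir: str | Path, base_dir: str | Path = ".") -> dict:
    """Execute the configured stages and return the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = Path(base_dir)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {"seed": seed, "stages": [], "inputs": {}, "outputs": [], "parameters": {}}
    summary_lines = [f"phosdyn run (seed {seed})"]

    def resolve(p):
        p = Path(p)
        if p.is_absolute():
            return p
        if (outdir / p.name).exists():
            return outdir / p.name
        return base / p

    def record_input(path: Path):
        manifest["inputs"][str(path)] = _digest(path)

    def record_output(path: Path):
        manifest["outputs"].append(str(path))

    for stage in cfg.get("stages", []):
        block = dict(cfg.get(stage, {}))
        manifest["stages"].append(stage)
        manifest["parameters"][stage] = {
            k: v for k, v in block.items() if not isinstance(v, (dict, list))
        }
        logger.info("[%s] starting", stage)
        try:
            if stage == "simulate_hdx":
                lines = _stage_simulate_hdx(block, seed, outdir, record_output)
            elif stage == "hotspot":
                lines = _stage_hotspot(block, resolve, outdir, record_input, record_output)
            elif stage == "hdx":
                lines = _stage_hdx(block, resolve, outdir, record_input, record_output)
            elif stage == "kinetics":
                lines = _stage_kinetics(block, resolve, outdir, record_input, record_output)
            elif stage == "structure":
                lines = _stage_structure(block, resolve, outdir, record_input, record_output)
        except (ConfigError, DataFormatError):
            raise
        except OSError as exc:
            raise DataFormatError(f"stage {stage!r} failed: {exc}") from exc
        summary_lines.extend(f"[{stage}] {ln}" for ln in lines)
        logger.info("[%s] done", stage)

    write_report(summary_lines, manifest, outdir)
    return manifest


def write_report(summary_lines: list[str], manifest: dict, outdir: Path) -> None:
    """Emit the human-readable summary and the machine-readable manifest."""
    report = outdir / "report.txt"
    report.write_text("\n".join(summary_lines) + "\n")
    manifest["outputs"].append(str(report))
    mpath = outdir / "manifest.json"
    manifest["outputs"].append(str(mpath))
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _stage_simulate_hdx(block, seed, outdir, record_output):
    length = int(block.get("protein_length", 120))
    states = block.get("states", ["WT", "VARIANT"])
    protection = block.get("protection", {st: 1000.0 for st in states})
    protection = {
        st: ({int(k): float(v) for k, v in spec.items()} if isinstance(spec, dict) else spec)
        for st, spec in protection.items()
    }
    cfg = simulate.HdxSimConfig(
        protein_length=length,
        sequence=block.get("sequence") or simulate.random_protein_sequence(length, seed),
        states=states,
        protection=protection,
        open_fraction=block.get("open_fraction", {}),
        base_protection=float(block.get("base_protection", 1000.0)),
        n_peptides=int(block.get("n_peptides", 30)),
        n_replicates=int(block.get("n_replicates", 3)),
        centroid_noise_sd=float(block.get("centroid_noise_sd", 0.0)),
        seed=seed,
    )
    pool, centroids = simulate.simulate_hdx_dataset(cfg)
    pool_path, cent_path = outdir / "pool.csv", outdir / "centroids.csv"
    pool.to_csv(pool_path, index=False)
    centroids.to_csv(cent_path, index=False)
    record_output(pool_path)
    record_output(cent_path)
    return [f"wrote {len(pool)} peptides, {len(centroids)} centroid rows"]


def _stage_hotspot(block, resolve, outdir, record_input, record_output):
    path = resolve(block["dataset"])
    record_input(path)
    records = hotspot.parse_phosphosite_dataset(path, block.get("organism"))
    table = hotspot.call_hotspots(records, q=float(block.get("q", 0.001)))
    ranked_path = outdir / "hotspots.csv"
    table.to_csv(ranked_path, index=False)
    record_output(ranked_path)
    prot = hotspot.summarize_protein_hotspots(table)
    prot_path = outdir / "hotspot_proteins.csv"
    prot.to_csv(prot_path, index=False)
    record_output(prot_path)
    lines = [f"{int(table['is_hotspot'].sum())} hotspots among {len(table)} sites"]
    if "differential" in block:
        dpath = resolve(block["differential"])
        record_input(dpath)
        diff = pd.read_csv(dpath)
        ranked, qrank = hotspot.rank_differential_sites(
            diff,
            alpha=float(block.get("alpha", 0.05)),
            direction=block.get("direction", "up"),
            query_site=block.get("query_site"),
        )
        diff_path = outdir / "differential_ranked.csv"
        ranked.to_csv(diff_path, index=False)
        record_output(diff_path)
        lines.append(f"differential: {len(ranked)} significant sites, query rank {qrank}")
    return lines


def _stage_hdx(block, resolve, outdir, record_input, record_output):
    for req in ("pool", "centroids", "protein_length", "reference_state"):
        if req not in block:
            raise ConfigError(f"hdx stage missing required key {req!r}")
    pool_path, cent_path = resolve(block["pool"]), resolve(block["centroids"])
    record_input(pool_path)
    record_input(cent_path)
    pool = pd.read_csv(pool_path)
    centroids = pd.read_csv(cent_path)
    pool, rejections = hdx.filter_peptide_pool(
        pool,
        min_len=int(block.get("min_len", 3)),
        max_len=int(block.get("max_len", 15)),
        max_charge=int(block.get("max_charge", 3)),
        ppm_tol=float(block.get("ppm_tol", 7.0)),
    )
    uptake = hdx.analyze_uptake(pool, centroids, d2o_fraction=float(block.get("d2o", 0.9)))
    length = int(block["protein_length"])
    levels = hdx.consolidate_residue_levels(uptake, pool, length)
    reference = block["reference_state"]
    outputs = {"uptake.csv": uptake, "pool_rejections.csv": rejections}
    lines = [f"{len(pool)} peptides kept, {len(rejections)} rejected"]
    variants = [s for s in levels["state"].unique() if s != reference]
    for variant in variants:
        emap = hdx.differential_exchange(levels, variant, reference)
        outputs[f"residue_map_{variant}.csv"] = emap.to_frame().sort_values("residue")
        segs = hdx.classify_exchange_regions(
            emap.dDbar,
            threshold=float(block.get("threshold", 5.0)),
            min_run=int(block.get("min_run", 3)),
        )
        outputs[f"segments_{variant}.csv"] = segs
        lines.append(f"{variant} vs {reference}: {len(segs)} segment(s)")
    summ = hdx.summarize_coverage(pool, length)
    outputs["hdx_summary.csv"] = pd.DataFrame(
        [{
            "coverage_pct": summ.coverage,
            "redundancy": summ.redundancy,
            "average_peptide_length": summ.average_peptide_length,
            "peptide_count": summ.peptide_count,
        }]
    )
    lines.append(
        f"coverage {summ.coverage:.1f}%, redundancy {summ.redundancy:.2f}, "
        f"{summ.peptide_count} peptides"
    )
    for name, df in outputs.items():
        path = outdir / name
        df.to_csv(path, index=False)
        record_output(path)
    return lines


def _stage_kinetics(block, resolve, outdir, record_input, record_output):
    lines = []
    rows = []
    if "rates" in block:
        path = resolve(block["rates"])
        record_input(path)
        rates = pd.read_csv(path)
        fit = kinetics.fit_michaelis_menten(rates, float(block["enzyme_conc"]))
        rows.append({
            "quantity": "mm_fit", "vmax": fit.vmax, "km_uM": fit.km,
            "kcat_per_s": fit.kcat, "specificity": fit.specificity,
            "converged": fit.converged,
        })
        lines.append(
            f"MM fit: Vmax={fit.vmax:.4g}, Km={fit.km:.4g} uM, "
            f"kcat={fit.kcat:.4g}/s, kcat/Km={fit.specificity:.4g}"
        )
    if "melt" in block:
        path = resolve(block["melt"])
        record_input(path)
        melt = pd.read_csv(path)
        tm = kinetics.find_tm(melt, window=int(block.get("window", 5)))
        rows.append({"quantity": "tm", "tm_C": tm.tm, "max_slope": tm.max_slope})
        lines.append(f"Tm = {tm.tm:.2f} C")
    if "activation" in block:
        path = resolve(block["activation"])
        record_input(path)
        curve = pd.read_csv(path)
        folds, max_fold, activatable = kinetics.activation_profile(
            curve, float(block.get("activatable_threshold", 1.5))
        )
        rows.append({
            "quantity": "activation", "max_fold": max_fold, "activatable": activatable,
        })
        lines.append(f"max activation {max_fold:.2f}x, activatable={activatable}")
    out = outdir / "kinetics_results.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    record_output(out)
    return lines


def _stage_structure(block, resolve, outdir, record_input, record_output):
    model_path = resolve(block["model"])
    record_input(model_path)
    model = structure.read_pdb(model_path, block.get("chain"))
    rows = []
    lines = []
    if "closed" in block and "open" in block:
        cpath, opath = resolve(block["closed"]), resolve(block["open"])
        record_input(cpath)
        record_input(opath)
        closed = structure.read_pdb(cpath, block.get("chain_closed"))
        open_ = structure.read_pdb(opath, block.get("chain_open"))
        label, rc, ro = structure.classify_conformation(model, closed, open_)
        rows.append({
            "quantity": "classification", "label": label,
            "rmsd_closed_A": rc, "rmsd_open_A": ro,
        })
        lines.append(f"classified {label} (closed {rc:.1f} A, open {ro:.1f} A)")
    elif "reference" in block:
        rpath = resolve(block["reference"])
        record_input(rpath)
        ref = structure.read_pdb(rpath, block.get("chain_ref"))
        res = structure.superpose_models(model, ref)
        rows.append({
            "quantity": "superposition", "rmsd_A": res.rmsd, "n_pairs": res.n_pairs,
        })
        lines.append(f"RMSD {res.rmsd:.1f} A over {res.n_pairs} C-alpha pairs")
    else:
        raise ConfigError("structure stage needs 'reference' or 'closed'+'open'")
    out = outdir / "structure_results.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    record_output(out)
    return lines
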