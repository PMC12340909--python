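"""Rigid-body structure superposition and conformer classification.

Reads protein coordinates from PDB files (first MODEL, ATOM records
only), pairs C-alpha atoms between two chains by residue-number
intersection, computes the optimal least-squares superposition by the
SVD-based Kabsch algorithm, and classifies a model as open or closed by
its RMSD against two reference structures (e.g. an autoinhibited
wild-type crystal structure versus an open activated-mutant structure).
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

from .errors import DataFormatError, NumericalError


@dataclass
class StructureModel:
    """Atom table of one model: chain, residue id, names, altloc, occupancy, xyz."""

    atoms: pd.DataFrame
    model_id: str = ""

    def calpha(self) -> pd.DataFrame:
        return self.atoms[self.atoms["atom_name"] == "CA"]


@dataclass
class SuperpositionResult:
    """Optimal rigid-body alignment of paired coordinate sets.

    ``rotation`` is a proper orthogonal 3x3 matrix and ``translation`` the
    vector such that ``R @ p + t`` best matches the target; ``degenerate``
    flags collinear/rank-deficient inputs whose rotation is not unique.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int
    paired_residues: list
    degenerate: bool = False


def read_pdb(path: str, chain: str | None = None) -> StructureModel:
    """Parse ATOM records of the first MODEL of a PDB file.

    HETATM records (waters, ligands) are ignored.  Alternate locations
    are resolved per (chain, residue, atom name) by highest occupancy,
    ties broken by altloc 'A' first then alphabetically.  ``chain``
    restricts to one chain; an empty selection is an error.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise DataFormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise DataFormatError(f"no models in {path}")
    model = st[0]
    rows = []
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            # gemmi marks HETATM via the residue's het_flag
            if res.het_flag != "A":
                continue
            for atom in res:
                rows.append(
                    (
                        ch.name,
                        res.seqid.num,
                        res.seqid.icode.strip(),
                        res.name,
                        atom.name,
                        atom.altloc.strip() if atom.altloc else "",
                        float(atom.occ),
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                    )
                )
    if not rows:
        where = f"chain {chain!r}" if chain else "file"
        raise DataFormatError(f"no ATOM records for {where} in {path}")
    df = pd.DataFrame(
        rows,
        columns=[
            "chain", "res_num", "icode", "res_name",
            "atom_name", "altloc", "occupancy", "x", "y", "z",
        ],
    )
    if not np.isfinite(df[["x", "y", "z"]].to_numpy()).all():
        raise DataFormatError(f"non-finite coordinates in {path}")
    # altloc resolution: highest occupancy wins, ties -> 'A' then alphabetical
    df["_altkey"] = df["altloc"].replace("", "A")
    df = df.sort_values(
        ["chain", "res_num", "icode", "atom_name", "occupancy", "_altkey"],
        ascending=[True, True, True, True, False, True],
        kind="stable",
    )
    df = df.drop_duplicates(["chain", "res_num", "icode", "atom_name"], keep="first")
    df = df.drop(columns="_altkey").reset_index(drop=True)
    return StructureModel(atoms=df, model_id=str(path))


def pair_common_calpha(
    a: StructureModel, b: StructureModel
) -> tuple[np.ndarray, np.ndarray, list]:
    """Paired C-alpha coordinate arrays over shared residues.

    Residues are matched by (residue number, insertion code) present in
    both models, in ascending residue order.  Fewer than 3 pairs is an
    insufficient-overlap error.
    """
    ca_a = a.calpha().set_index(["res_num", "icode"])
    ca_b = b.calpha().set_index(["res_num", "icode"])
    common = sorted(set(ca_a.index) & set(ca_b.index))
    if len(common) < 3:
        raise DataFormatError(
            f"insufficient C-alpha overlap: {len(common)} shared residue(s), need >= 3"
        )
    pa = ca_a.loc[common, ["x", "y", "z"]].to_numpy(dtype=float)
    pb = ca_b.loc[common, ["x", "y", "z"]].to_numpy(dtype=float)
    return pa, pb, common


def kabsch_superpose(P: np.ndarray, Q: np.ndarray, paired_residues: list | None = None) -> SuperpositionResult:
    """Least-squares rigid superposition of P onto Q (Kabsch/SVD).

    Centroids are subtracted, the optimal proper rotation is obtained
    from the SVD of the covariance matrix with a sign correction on the
    smallest singular vector (no reflections), and the RMSD is evaluated
    on the transformed coordinates.  Degenerate (rank-deficient) inputs
    return a flagged result whose rotation is not meaningful.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise DataFormatError(f"coordinate arrays must both be (n, 3); got {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise DataFormatError(f"need at least 3 paired atoms, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    degenerate = S[1] <= 1e-10 * max(S[0], 1.0)  # rank < 2: rotation not unique
    t = cq - R @ cp
    diff = Pc @ R.T - Qc
    rmsd = float(np.sqrt(np.sum(diff**2) / n))
    return SuperpositionResult(
        rotation=R,
        translation=t,
        rmsd=rmsd,
        n_pairs=n,
        paired_residues=list(paired_residues) if paired_residues is not None else [],
        degenerate=bool(degenerate),
    )


def superpose_models(
    a: StructureModel, b: StructureModel
) -> SuperpositionResult:
    """Superpose model ``a`` onto ``b`` over their common C-alpha atoms."""
    pa, pb, common = pair_common_calpha(a, b)
    return kabsch_superpose(pa, pb, paired_residues=common)


def classify_conformation(
    model: StructureModel | np.ndarray,
    closed_ref: StructureModel | np.ndarray,
    open_ref: StructureModel | np.ndarray,
) -> tuple[str, float, float]:
    """Label a model open or closed by nearest-reference RMSD.

    Superposes the model onto each reference (common C-alpha for
    StructureModels, direct pairing for bare coordinate arrays) and
    returns (label, rmsd_closed, rmsd_open); an exact tie is
    ``'ambiguous'``.
    """
    rmsd_closed = _rmsd_to(model, closed_ref)
    rmsd_open = _rmsd_to(model, open_ref)
    if rmsd_closed < rmsd_open:
        label = "closed"
    elif rmsd_open < rmsd_closed:
        label = "open"
    else:
        label = "ambiguous"
    return label, rmsd_closed, rmsd_open


def _rmsd_to(model, ref) -> float:
    if isinstance(model, StructureModel) and isinstance(ref, StructureModel):
        return superpose_models(model, ref).rmsd
    return kabsch_superpose(np.asarray(model), np.asarray(ref)).rmsd


def transform_coordinates(model: StructureModel, result: SuperpositionResult) -> StructureModel:
    """Apply a superposition's rotation/translation to all atoms of a model."""
    xyz = model.atoms[["x", "y", "z"]].to_numpy(dtype=float)
    moved = xyz @ result.rotation.T + result.translation
    atoms = model.atoms.copy()
    atoms[["x", "y", "z"]] = moved
    return StructureModel(atoms=atoms, model_id=model.model_id + "|superposed")


def write_pdb(model: StructureModel, path: str) -> None:
    """Write an atom table back out as minimal PDB ATOM records."""
    with open(path, "w") as fh:
        for i, row in enumerate(model.atoms.itertuples(index=False), start=1):
            name = row.atom_name
            name_field = f" {name:<3s}" if len(name) < 4 else name
            fh.write(
                f"ATOM  {i:5d} {name_field}{'':1s}{row.res_name:<3s} {row.chain:1s}"
                f"{row.res_num:4d}{row.icode or '':1s}   "
                f"{row.x:8.3f}{row.y:8.3f}{row.z:8.3f}{row.occupancy:6.2f}{0.0:6.2f}\n"
            )
        fh.write("END\n")
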