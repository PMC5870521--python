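"""End-to-end analysis pipeline: files in, structured report out.

Stage order follows the standard comparative-morphometrics workflow:
missing-landmark estimation -> Procrustes superimposition with object
symmetry -> symmetric component -> PCA -> Procrustes ANOVA -> group mean
shapes and Procrustes distances -> disparity / partial disparity ->
species means -> phylogenetic signal (K) -> phylogenetic ANOVA ->
phylomorphospace -> UPGMA phenogram and discordance screen -> convergence
metrics.  Tree-dependent stages are skipped (with a note in the report)
when no tree is configured.

Every stochastic stage draws from its own substream of one root seed, so a
rerun with the same config and seed regenerates every numeric table
byte-identically.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .convergence import convergence_table
from .geometry import (
    AlignedDataset,
    LandmarkConfiguration,
    estimate_missing_tps,
    gpa,
    procrustes_distance,
    symmetric_gpa,
)
from .io import read_landmarks_csv, read_metadata_csv, read_symmetry_json
from .phylo import (
    Phylogeny,
    ancestral_states,
    discordant_pairs,
    kmult,
    normalize_label,
    pgls_anova,
    phylomorphospace,
    species_means,
    upgma,
)
from .stats import disparity, mean_shape, procrustes_anova, shape_pca

__all__ = ["AnalysisConfig", "validate_inputs", "run_pipeline", "estimate_missing_dataset"]


@dataclass
class AnalysisConfig:
    landmarks: str
    metadata: str
    symmetry: str | None = None
    tree: str | None = None
    focal_pairs: str | None = None
    out_dir: str = "results/pipeline"
    include_outgroup_in_gpa: bool = True
    exclude_groups_from_disparity: tuple[str, ...] = ()
    scale: bool = True
    anova_factor: str = "habitat"
    disparity_factors: tuple[str, ...] = ("habitat", "genus")
    n_perm_anova: int = 1000
    n_perm_pgls: int = 999
    n_perm_kmult: int = 1000
    n_sim_cmetrics: int = 1000
    seed: int | None = None

    def __post_init__(self):
        for path in (self.landmarks, self.metadata, self.symmetry, self.tree,
                     self.focal_pairs):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)
        if self.seed is None:
            raise ValueError("a seed is required: permutation stages are stochastic")


def validate_inputs(config: AnalysisConfig) -> list[str]:
    """Reconcile landmarks, metadata, symmetry map and tree; list every issue."""
    issues: list[str] = []
    configs = read_landmarks_csv(config.landmarks)
    meta = read_metadata_csv(config.metadata)
    k_counts = {c.n_landmarks for c in configs}
    if len(k_counts) > 1:
        issues.append(f"inconsistent landmark counts across specimens: {sorted(k_counts)}")
    ids_l = {c.specimen_id for c in configs}
    ids_m = set(meta["specimen_id"])
    for sid in sorted(ids_l - ids_m):
        issues.append(f"specimen {sid!r} has landmarks but no metadata")
    for sid in sorted(ids_m - ids_l):
        issues.append(f"specimen {sid!r} has metadata but no landmarks")
    # a row with empty coordinate cells is *marked* missing (valid, will be
    # TPS-estimated); an entirely absent row is an unmarked gap and is flagged
    raw = pd.read_csv(config.landmarks, dtype={"specimen_id": str})
    k_max = max(k_counts)
    for sid, grp in raw.groupby("specimen_id", sort=False):
        absent = sorted(set(range(1, k_max + 1)) - set(grp["landmark"].astype(int)))
        if absent:
            issues.append(
                f"specimen {sid!r}: landmarks {absent} absent with no missing marker"
            )
    for c in configs:
        if c.present_mask.sum() < 4:
            issues.append(
                f"specimen {c.specimen_id!r}: only {int(c.present_mask.sum())} "
                "present landmarks; cannot estimate the rest"
            )
    if config.symmetry is not None:
        smap = read_symmetry_json(config.symmetry)
        try:
            smap.validate_for(max(k_counts))
        except ValueError as exc:
            issues.append(f"symmetry map: {exc}")
    if "habitat" in meta.columns:
        from .io import METADATA_HABITATS

        bad = sorted(set(meta["habitat"]) - set(METADATA_HABITATS) - {""})
        if bad:
            issues.append(f"habitat values outside controlled vocabulary: {bad}")
    if config.tree is not None:
        tree = Phylogeny.from_file(config.tree)
        species = {normalize_label(s) for s in meta["species"]}
        tips = set(tree.tip_labels)
        for t in sorted(tips - species):
            issues.append(f"tree tip {t!r} absent from metadata species")
        for s in sorted(species - tips):
            issues.append(f"species {s!r} absent from tree tips")
    return issues


def estimate_missing_dataset(
    configs: list[LandmarkConfiguration],
    species: dict[str, str],
    min_complete_per_species: int = 3,
) -> list[LandmarkConfiguration]:
    """Fill missing landmarks per specimen with TPS against a consensus.

    The reference is the GPA consensus of the complete specimens of the same
    species when at least ``min_complete_per_species`` exist, otherwise the
    consensus of all complete specimens.  Because the spline's affine part
    absorbs any similarity transform, the reference's frame is immaterial.
    """
    complete = [c for c in configs if c.is_complete]
    if not complete:
        raise ValueError("no complete specimens to build a TPS reference from")
    if len(complete) == 1:
        global_ref = complete[0].coords
    else:
        global_ref = gpa(complete, scale=True).consensus
    by_species: dict[str, list[LandmarkConfiguration]] = {}
    for c in complete:
        by_species.setdefault(species.get(c.specimen_id, ""), []).append(c)
    refs: dict[str, np.ndarray] = {}
    out = []
    for c in configs:
        if c.is_complete:
            out.append(c)
            continue
        sp = species.get(c.specimen_id, "")
        peers = by_species.get(sp, [])
        if len(peers) >= min_complete_per_species:
            if sp not in refs:
                refs[sp] = gpa(peers, scale=True).consensus if len(peers) > 1 else peers[0].coords
            ref = refs[sp]
        else:
            ref = global_ref
        out.append(estimate_missing_tps(c, ref))
    return out


def _group_distances(aligned: AlignedDataset, labels: np.ndarray) -> pd.DataFrame:
    groups = sorted(set(labels))
    mat = pd.DataFrame(0.0, index=groups, columns=groups)
    means = {g: mean_shape(aligned, np.asarray(labels) == g) for g in groups}
    for a, b in itertools.combinations(groups, 2):
        d = procrustes_distance(means[a], means[b])
        mat.loc[a, b] = mat.loc[b, a] = d
    return mat


def _anova_frame(res) -> pd.DataFrame:
    rows = [
        {
            "term": t.name, "df": t.df, "SS": t.ss, "MS": t.ms, "F": t.f,
            "Z": t.z_score, "p": t.p_value,
        }
        for t in res.terms
    ]
    rows.append(
        {"term": "residual", "df": res.df_residual, "SS": res.ss_residual,
         "MS": res.ss_residual / res.df_residual, "F": np.nan, "Z": np.nan,
         "p": np.nan}
    )
    return pd.DataFrame(rows)


def _disparity_frame(rep) -> pd.DataFrame:
    rows = [
        {
            "group": g,
            "n": rep.group_n[g],
            "partial_disparity": rep.group_pd[g],
            "partial_disparity_pct": rep.group_pd_percent[g],
            "procrustes_variance": rep.group_variance[g],
        }
        for g in rep.group_pd
    ]
    df = pd.DataFrame(rows)
    df.attrs["overall_md"] = rep.overall_md
    return df


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run every stage; write per-stage CSVs plus one JSON master report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(8)
    rngs = [np.random.default_rng(s) for s in seeds]
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: str(v) for k, v in vars(config).items()},
        "stages": {},
    }

    configs = read_landmarks_csv(config.landmarks)
    meta = read_metadata_csv(config.metadata).set_index("specimen_id", drop=False)
    smap = read_symmetry_json(config.symmetry) if config.symmetry else None
    tree = Phylogeny.from_file(config.tree) if config.tree else None

    # missing landmarks
    n_incomplete = sum(not c.is_complete for c in configs)
    if n_incomplete:
        species_of = dict(zip(meta["specimen_id"], meta["species"]))
        configs = estimate_missing_dataset(configs, species_of)
    report["stages"]["estimate_missing"] = {"n_estimated": n_incomplete}

    # superimposition (object symmetry when a map is given)
    if smap is not None:
        aligned = symmetric_gpa(configs, smap, scale=config.scale)
    else:
        aligned = gpa(configs, scale=config.scale)
    order = aligned.specimen_ids
    meta = meta.loc[order]
    report["stages"]["gpa"] = {
        "n_specimens": aligned.n_specimens,
        "n_landmarks": aligned.n_landmarks,
        "object_symmetry": smap is not None,
    }

    # PCA morphospace
    pca = shape_pca(aligned)
    scores = pd.DataFrame(
        pca.scores,
        index=pd.Index(order, name="specimen_id"),
        columns=[f"PC{i + 1}" for i in range(pca.scores.shape[1])],
    )
    scores.to_csv(out_dir / "pca_scores.csv")
    pd.DataFrame(
        {"PC": scores.columns, "percent_variance": pca.percent_variance}
    ).to_csv(out_dir / "pca_percent_variance.csv", index=False)
    report["stages"]["pca"] = {
        "pc1_pct": float(pca.percent_variance[0]),
        "pc1_pc2_pct": float(pca.percent_variance[:2].sum()),
    }

    # Procrustes ANOVA on the configured factor
    factor = config.anova_factor
    anova_res = None
    if factor in meta.columns and meta[factor].nunique() > 1:
        labels = meta[factor].to_numpy()
        anova_res = procrustes_anova(
            aligned, {factor: labels}, n_perm=config.n_perm_anova, seed=rngs[0]
        )
        _anova_frame(anova_res).to_csv(out_dir / "procrustes_anova.csv", index=False)
        term = anova_res.terms[0]
        report["stages"]["procrustes_anova"] = {
            "factor": factor, "F": term.f, "Z": term.z_score, "p": term.p_value,
        }
        _group_distances(aligned, labels).to_csv(out_dir / f"procdist_{factor}.csv")

    # disparity (optionally excluding designated groups, e.g. an outgroup)
    for fac in config.disparity_factors:
        if fac not in meta.columns:
            continue
        keep = ~meta[fac].isin(config.exclude_groups_from_disparity).to_numpy()
        sub = aligned.subset(keep)
        rep = disparity(sub, meta.loc[keep, fac].to_numpy())
        frame = _disparity_frame(rep)
        frame.to_csv(out_dir / f"disparity_{fac}.csv", index=False)
        report["stages"][f"disparity_{fac}"] = {
            "overall_md": rep.overall_md,
            "partial_disparity_pct": rep.group_pd_percent,
        }

    if tree is None:
        report["stages"]["phylogenetic"] = "skipped: no tree configured"
        _write_report(report, out_dir)
        return report

    # species means matched to tree tips
    sm = species_means(aligned, meta["species"].to_numpy(), tree)
    sm.to_csv(out_dir / "species_means.csv")

    # phylogenetic signal
    sig = kmult(sm, tree, n_perm=config.n_perm_kmult, seed=rngs[1])
    report["stages"]["kmult"] = {"K": sig.k_statistic, "p": sig.p_value}

    # phylogenetic ANOVA
    if factor in meta.columns and meta[factor].nunique() > 1:
        hab_sp = meta.groupby("species")[factor].first()
        hab_sp.index = [normalize_label(s) for s in hab_sp.index]
        labels_sp = hab_sp.loc[sm.index].to_numpy()
        pgls_res = pgls_anova(
            sm, tree, {factor: labels_sp}, n_perm=config.n_perm_pgls, seed=rngs[2]
        )
        _anova_frame(pgls_res).to_csv(out_dir / "pgls_anova.csv", index=False)
        term = pgls_res.terms[0]
        report["stages"]["pgls_anova"] = {
            "factor": factor, "F": term.f, "Z": term.z_score, "p": term.p_value,
        }

    # phylomorphospace from species-mean PCA and ML ancestral states
    sp_pca = shape_pca(sm.to_numpy())
    anc = ancestral_states(sm, tree)
    nodes, edges = phylomorphospace(sp_pca, anc, tree)
    nodes.to_csv(out_dir / "phylomorphospace_nodes.csv")
    edges.to_csv(out_dir / "phylomorphospace_edges.csv", index=False)

    # UPGMA phenogram from species-mean Procrustes distances + discordance screen
    smv = sm.to_numpy()
    dmat = np.linalg.norm(smv[:, None, :] - smv[None, :, :], axis=-1)
    dmat_df = pd.DataFrame(dmat, index=sm.index, columns=sm.index)
    phen = upgma(dmat_df)
    (out_dir / "phenogram.nwk").write_text(phen.newick() + "\n")
    (out_dir / "tree_echo.nwk").write_text(tree.newick() + "\n")
    screen = discordant_pairs(tree, phen)
    screen.to_csv(out_dir / "discordant_pairs.csv", index=False)
    report["stages"]["phenogram"] = {"n_discordant": int(len(screen))}

    # convergence metrics for the configured focal pairs
    if config.focal_pairs:
        pairs_df = pd.read_csv(config.focal_pairs, dtype=str)
        pairs = list(zip(pairs_df["tip_a"], pairs_df["tip_b"]))
        conv = convergence_table(
            sm, tree, pairs, n_sim=config.n_sim_cmetrics, seed=rngs[3]
        )
        conv.to_csv(out_dir / "convergence.csv", index=False)
        report["stages"]["convergence"] = {
            "n_pairs": len(pairs), "n_sim": config.n_sim_cmetrics,
        }

    _write_report(report, out_dir)
    return report


def _write_report(report: dict, out_dir: Path) -> None:
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
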