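"""Superimpose the study landmarks and chart the morphospace.

Fills missing landmarks by TPS against per-species consensus, runs GPA with
object symmetry, checks measurement error on the replicated specimens
(individual vs replicate Procrustes ANOVA), then — on one measurement per
individual — computes the PCA morphospace, the habitat Procrustes ANOVA
with 1000 RRPP permutations, and habitat mean-shape Procrustes distances.
"""

from pathlib import Path

import pandas as pd

from phylomorph.geometry import symmetric_gpa
from phylomorph.io import read_landmarks_csv, read_metadata_csv, read_symmetry_json
from phylomorph.pipeline import _anova_frame, _group_distances, estimate_missing_dataset
from phylomorph.stats import procrustes_anova, shape_pca

STUDY = Path(__file__).resolve().parents[1] / "results" / "study"
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    configs = read_landmarks_csv(STUDY / "landmarks.csv")
    meta = read_metadata_csv(STUDY / "metadata.csv").set_index(
        "specimen_id", drop=False
    )
    smap = read_symmetry_json(STUDY / "symmetry.json")

    n_incomplete = sum(not c.is_complete for c in configs)
    configs = estimate_missing_dataset(
        configs, dict(zip(meta["specimen_id"], meta["species"]))
    )
    print(f"estimated missing landmarks for {n_incomplete} configurations")

    aligned_all = symmetric_gpa(configs, smap)
    meta = meta.loc[aligned_all.specimen_ids]

    # measurement error: individual vs replicate on the replicated subset
    rep_mask = (meta["replicate_id"] != "").to_numpy()
    if rep_mask.sum():
        rep_ds = aligned_all.subset(rep_mask)
        rep_meta = meta.loc[rep_mask]
        me = procrustes_anova(
            rep_ds, {"individual": rep_meta["individual_id"].to_numpy()},
            n_perm=999, seed=101,
        )
        _anova_frame(me).to_csv(OUT / "measurement_error_anova.csv", index=False)
        t = me.term("individual")
        print(
            f"measurement error: among-individual F = {t.f:.2f} (p = {t.p_value:.4g});"
            " residual variance is replicate (digitizing) error"
        )

    # one measurement per individual for the main analyses
    keep = meta["replicate_id"].astype(str).isin(["", "1"]).to_numpy()
    aligned = aligned_all.subset(keep)
    meta1 = meta.loc[keep]

    pca = shape_pca(aligned)
    pd.DataFrame(
        pca.scores,
        index=pd.Index(aligned.specimen_ids, name="specimen_id"),
        columns=[f"PC{i + 1}" for i in range(pca.scores.shape[1])],
    ).to_csv(OUT / "pca_scores.csv")
    pd.DataFrame(
        {"PC": [f"PC{i + 1}" for i in range(len(pca.percent_variance))],
         "percent_variance": pca.percent_variance}
    ).to_csv(OUT / "pca_percent_variance.csv", index=False)
    print(
        f"morphospace: PC1 {pca.percent_variance[0]:.1f}%, "
        f"PC2 {pca.percent_variance[1]:.1f}% "
        f"(PC1+PC2 = {pca.percent_variance[:2].sum():.1f}% of shape variance)"
    )

    hab = meta1["habitat"].to_numpy()
    res = procrustes_anova(aligned, {"habitat": hab}, n_perm=1000, seed=202)
    _anova_frame(res).to_csv(OUT / "procrustes_anova_habitat.csv", index=False)
    t = res.terms[0]
    print(f"habitat Procrustes ANOVA: F = {t.f:.3f}, Z = {t.z_score:.3f}, p = {t.p_value:.4g}")

    dmat = _group_distances(aligned, hab)
    dmat.to_csv(OUT / "procrustes_distances_habitat.csv")
    far = dmat.stack().idxmax()
    print(f"largest habitat mean-shape distance: {far[0]}-{far[1]} = {dmat.loc[far]:.4f}")

    aligned_ids = pd.DataFrame({
        "specimen_id": aligned.specimen_ids,
        "centroid_size": aligned.centroid_sizes,
    })
    aligned_ids.to_csv(OUT / "centroid_sizes.csv", index=False)


if __name__ == "__main__":
    main()
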