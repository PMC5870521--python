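"""Phylogenetically informed analyses of the species mean shapes.

Computes the multivariate phylogenetic-signal statistic K (1000
permutations), the phylogenetic ANOVA of shape on habitat (GLS transform +
999 RRPP permutations) for contrast with the ordinary ANOVA of step 02, the
phylomorphospace coordinates (tips + ML ancestral states on PC1-PC2), and
the UPGMA phenogram from species-mean Procrustes distances together with
the tanglegram discordance screen that nominates candidate convergent
pairs.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from phylomorph.geometry import symmetric_gpa
from phylomorph.io import read_landmarks_csv, read_metadata_csv, read_symmetry_json
from phylomorph.phylo import (
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
from phylomorph.pipeline import _anova_frame, estimate_missing_dataset
from phylomorph.stats import shape_pca

STUDY = Path(__file__).resolve().parents[1] / "results" / "study"
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    configs = read_landmarks_csv(STUDY / "landmarks.csv")
    meta = read_metadata_csv(STUDY / "metadata.csv").set_index(
        "specimen_id", drop=False
    )
    smap = read_symmetry_json(STUDY / "symmetry.json")
    tree = Phylogeny.from_file(STUDY / "tree.nwk")
    configs = estimate_missing_dataset(
        configs, dict(zip(meta["specimen_id"], meta["species"]))
    )
    aligned_all = symmetric_gpa(configs, smap)
    meta = meta.loc[aligned_all.specimen_ids]
    keep = meta["replicate_id"].astype(str).isin(["", "1"]).to_numpy()
    aligned = aligned_all.subset(keep)
    meta = meta.loc[keep]

    sm = species_means(aligned, meta["species"].to_numpy(), tree)
    sm.to_csv(OUT / "species_means.csv")

    sig = kmult(sm, tree, n_perm=1000, seed=303)
    print(f"phylogenetic signal: K = {sig.k_statistic:.4f}, p = {sig.p_value:.4g}")

    hab = meta.groupby("species")["habitat"].first()
    hab.index = [normalize_label(s) for s in hab.index]
    labels = hab.loc[sm.index].to_numpy()
    res = pgls_anova(sm, tree, {"habitat": labels}, n_perm=999, seed=404)
    _anova_frame(res).to_csv(OUT / "pgls_anova_habitat.csv", index=False)
    t = res.terms[0]
    print(
        f"phylogenetic ANOVA (habitat): F = {t.f:.3f}, Z = {t.z_score:.3f}, "
        f"p = {t.p_value:.4g}"
    )

    pca = shape_pca(sm.to_numpy())
    anc = ancestral_states(sm, tree)
    nodes, edges = phylomorphospace(pca, anc, tree)
    nodes.to_csv(OUT / "phylomorphospace_nodes.csv")
    edges.to_csv(OUT / "phylomorphospace_edges.csv", index=False)

    smv = sm.to_numpy()
    dmat = pd.DataFrame(
        np.linalg.norm(smv[:, None, :] - smv[None, :, :], axis=-1),
        index=sm.index, columns=sm.index,
    )
    phen = upgma(dmat)
    (OUT / "phenogram.nwk").write_text(phen.newick() + "\n")
    screen = discordant_pairs(tree, phen)
    screen.to_csv(OUT / "discordant_pairs.csv", index=False)
    if len(screen):
        top = screen.iloc[0]
        print(
            f"tanglegram screen: {len(screen)} discordant phenogram sister pair(s); "
            f"most distant on the phylogeny: {top['tip_a']} + {top['tip_b']} "
            f"(patristic distance {top['phylo_distance']:.3f})"
        )
    else:
        print("tanglegram screen: no discordant phenogram sister pairs")


if __name__ == "__main__":
    main()
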