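# locsurf

Local functional surface descriptors for ligand binding-site prediction on
molecular surface meshes.

## The problem

Molecular recognition happens at the surface: a ligand binds where the
protein presents the right local arrangement of shape, chemistry and
electrostatics, regardless of which residues or fold produce it. `locsurf`
is for structural bioinformaticians who want to compare protein surface
regions — and predict ligand-specific binding interfaces — **without** using
sequence, residue identities, or pre-identified pockets. Given a query
surface it returns a probability, for every surface point, that the point
belongs to an interface with the target ligand.

## The method

A solvent-excluded surface mesh (e.g. from MSMS, at ≈3 vertices/Å²) is
turned into a field of 40-feature descriptors, one per vertex: visibility,
distances to 12 chemical atom categories and to the nearest H-bond
donor/acceptor, and five multi-scale patch statistics (curvature,
anisotropy, curvature variance, hydropathy, electrostatic potential) over
geodesic discs of radius 1.6, 3.2, 4.8, 6.4 and 8 Å. Features are z-scored
against a reference corpus.

For a target ligand, split into rigid moieties, the model holds one
RBF-SVM per moiety atom A, trained on samples within 1.6 Å of the atom's
van der Waals surface in example complexes (equal-sized random negatives),
plus the observed distance bounds [min_AB, max_AB] for every atom pair.
Prediction runs fine-to-coarse:

1. group redundant samples per atom under its important features
   (variance < 1 over the positives);
2. score representatives with the atom classifier → P_A;
3. confirm across atoms: PC_A(s) = P_A(s) · mean_B conf_B(s), where
   conf_B(s) averages P_B over samples at a pairwise-plausible distance
   (window [min_AB − r, max_AB + r], relaxed by the grouping radius r;
   empty window ⇒ 0; pairs with min_AB > 15 Å never combine);
4. merge: P_M = max_A PC_A, and P(s) = max_{M∈L} P_M(s).

Evaluation labels a vertex as interface when within 1.6 Å of the vdW
surface of any bound-ligand atom, and scores fields by ROC and
precision–recall areas.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

Everything is testable without downloads: the `fixtures` module generates
synthetic complexes — pseudo-proteins with a surface mesh, a two-atom
pseudo-ligand posed on it, and a planted per-atom feature signature
(+2 sd on 5 features by default) at the true interface vertices.

```python
import numpy as np
from locsurf import (make_synthetic_corpus, MoietySpec, build_ligand_model,
                     apply_normalization, predict_ligand, label_interface,
                     roc, precision_recall)
from locsurf.training import TrainingExample

corpus = make_synthetic_corpus(12, seed=7, template={"spacing_range": (3.5, 4.5)})
train, test = corpus[:10], corpus[10:]

spec = MoietySpec("toy", ["L1", "L2"], ["LIG"])
examples = [TrainingExample(c.surface, c.ligand_pose, f"train{i}")
            for i, c in enumerate(train)]
model = build_ligand_model("LIG", [spec], {"toy": examples}, seed=0)

lo, hi = model.moieties[0].bounds.get("L1", "L2")
print(f"observed L1-L2 distance bounds: {lo:.2f}-{hi:.2f} A")

cx = test[0]
surface = apply_normalization(cx.surface, model.stats)
result = predict_ligand(surface, model)
labels = label_interface(cx.mesh, cx.ligand_pose)
print(f"surface samples: {surface.mesh.n_vertices}, interface points: {labels.sum()}")
print(f"ROC area: {roc(result.field, labels).roc_area:.3f}")
print(f"PR area: {precision_recall(result.field, labels).pr_area:.3f}")
```

Output:

```
observed L1-L2 distance bounds: 3.49-4.12 A
surface samples: 603, interface points: 62
ROC area: 0.999
PR area: 0.993
```

The recovered distance bounds sit inside the generative jitter window
(3.5–4.5 Å, up to mesh resolution); ROC/PR areas near 1 mean the planted
interface is ranked above essentially all background surface on held-out
complexes.

A command-line interface wraps the same pipeline for shell use:

```sh
locsurf synth mesh --kind sphere --radius 5 -o sphere.off
locsurf describe --mesh surf.vert --pdb protein.pdb --dx pot.dx -o surf.json
locsurf fit-stats surf1.json surf2.json -o stats.json
locsurf predict --surface surf.json --model model.json -o field.json
locsurf evaluate --field field.json --surface surf.json --pdb complex.pdb
```

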