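"""Desk-scale synthetic fixtures with the structure the pipeline assumes.

Three generators emulate the three external inputs:

* plate-structured L1000 Level-3 profiles — per-plate empty-vector controls
  plus shRNA knockdown profiles that share a planted per-gene expression
  shift across shRNAs and replicates;
* pairwise SL scores — a hidden symmetric bilinear rule over a small set of
  informative signature dimensions, so the labels are learnable from the
  signatures and the informative dimensions are recoverable by saliency;
* a PPI edge list — a stochastic block model whose communities follow the
  latent factors of the SL rule.

Everything is driven by one integer seed and is fully deterministic;
re-generating a fixture yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .signatures import build_gene_signatures, profiles_from_frames, signatures_to_frame


@dataclass
class FixtureSpec:
    """Knobs of the synthetic study; defaults are the documented conditions."""

    n_genes: int = 120
    n_plates: int = 6
    n_shrnas_per_gene: int = 2
    n_replicates: int = 3
    n_landmark: int = 978          # reducible for fast unit tests
    n_controls_per_plate: int = 16
    k_latent: int = 8              # latent dimension of the planted SL rule
    informative_dims: tuple = ()   # empty -> first 20 dimensions
    noise_sd: float = 0.1          # measurement noise, expression units
    shift_scale: float = 0.3       # sd of the planted per-gene shift
    plate_sd: float = 0.2          # plate batch effect
    shrna_sd: float = 0.05         # shRNA off-target offset
    score_noise: float = 0.05      # SL score noise, fraction of signal sd
    additive_weight: float = 1.0   # per-gene main-effect strength of the SL rule
    interaction_weight: float = 0.5  # bilinear interaction strength
    pos_frac: float = 0.05
    neg_frac: float = 0.5
    seed: int = 0

    def resolved_informative_dims(self) -> np.ndarray:
        if len(self.informative_dims):
            dims = np.asarray(self.informative_dims, dtype=int)
        else:
            dims = np.arange(min(20, self.n_landmark))
        if dims.max(initial=-1) >= self.n_landmark:
            raise ValueError("informative_dims outside the landmark range")
        return dims

    def gene_names(self) -> list[str]:
        return [f"G{i:03d}" for i in range(self.n_genes)]


def generate_l1000_plates(spec: FixtureSpec):
    """Simulate Level-3 plates: controls + shRNA profiles with planted shifts.

    Returns ``(expression, metadata, truth)`` where expression is a
    landmarks x samples frame, metadata the matching sample table, and truth
    carries the planted per-gene shifts (genes x landmarks).
    """
    rng = np.random.default_rng([spec.seed, 1])
    genes = spec.gene_names()
    landmarks = [f"L{i:03d}" for i in range(spec.n_landmark)]

    baseline = rng.normal(9.0, 1.0, size=spec.n_landmark)
    plate_effects = rng.normal(0.0, spec.plate_sd, size=(spec.n_plates, spec.n_landmark))
    shifts = rng.normal(0.0, spec.shift_scale, size=(spec.n_genes, spec.n_landmark))

    columns, meta_rows = [], []
    values = []
    for p in range(spec.n_plates):
        for c in range(spec.n_controls_per_plate):
            sid = f"CTL_{p:02d}_{c:02d}"
            columns.append(sid)
            values.append(baseline + plate_effects[p]
                          + rng.normal(0.0, spec.noise_sd, spec.n_landmark))
            meta_rows.append((sid, f"PLATE{p:02d}", "vector_control", "", "", 96))

    counter = 0
    for gi, gene in enumerate(genes):
        for s in range(spec.n_shrnas_per_gene):
            shrna = f"{gene}_sh{s}"
            off_target = rng.normal(0.0, spec.shrna_sd, spec.n_landmark)
            for r in range(spec.n_replicates):
                p = counter % spec.n_plates
                counter += 1
                sid = f"{shrna}_r{r}"
                columns.append(sid)
                values.append(baseline + plate_effects[p] + shifts[gi] + off_target
                              + rng.normal(0.0, spec.noise_sd, spec.n_landmark))
                meta_rows.append((sid, f"PLATE{p:02d}", "shRNA", gene, shrna, 96))

    expression = pd.DataFrame(np.array(values).T, index=landmarks, columns=columns)
    metadata = pd.DataFrame(meta_rows, columns=eio.META_COLUMNS)
    truth = {"shifts": pd.DataFrame(shifts, index=genes, columns=landmarks)}
    return expression, metadata, truth


def _latent_embedding(spec: FixtureSpec, signatures: pd.DataFrame) -> np.ndarray:
    """tanh-squashed random linear map of the informative signature block."""
    rng = np.random.default_rng([spec.seed, 2])
    dims = spec.resolved_informative_dims()
    x = signatures.to_numpy(dtype=float)[:, dims]
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x - mu) / sd
    a = rng.normal(0.0, 1.0 / np.sqrt(len(dims)), size=(spec.k_latent, len(dims)))
    return np.tanh(x @ a.T)


def generate_sl_scores(spec: FixtureSpec, signatures: pd.DataFrame):
    """Pairwise SL scores from a hidden symmetric bilinear rule.

    t_ij = g~(f_i)^T M g~(f_j) + noise, where g~ = [1, g(f)] appends a
    constant component to the tanh embedding of the informative dimensions.
    The symmetric M therefore contributes a per-gene main effect (its first
    row/column) alongside the bilinear interaction (its remaining block);
    ``additive_weight`` and ``interaction_weight`` set the two strengths.
    The main effect keeps the ranking learnable by pair scorers that are
    additive across the two genes, while the interaction block is what makes
    the task non-trivial. Scores are median-centered so the sign/rank
    thresholds of the labeling rule yield non-empty positive and negative
    sets. Returns ``(scores, truth)`` with the noiseless pair ranking stored
    for oracle checks.
    """
    rng = np.random.default_rng([spec.seed, 3])
    g = _latent_embedding(spec, signatures)
    w = rng.normal(0.0, 1.0, size=spec.k_latent)        # M's first row: main effect
    m = rng.normal(0.0, 1.0, size=(spec.k_latent, spec.k_latent))
    m = (m + m.T) / 2.0                                  # M's interaction block
    phi = g @ w
    add_full = phi[:, None] + phi[None, :]
    int_full = g @ m @ g.T
    genes = list(signatures.index)
    iu, ju = np.triu_indices(len(genes), k=1)
    add_part, int_part = add_full[iu, ju], int_full[iu, ju]
    add_part = add_part / add_part.std()
    int_part = int_part / int_part.std()
    t = spec.additive_weight * add_part + spec.interaction_weight * int_part
    noise = rng.normal(0.0, spec.score_noise * t.std(), size=t.shape)
    scored = t + noise
    scored = scored - np.median(scored)
    rows = [(genes[i], genes[j], s, "SYN") for i, j, s in zip(iu, ju, scored)]
    scores = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score", "cell_line"])
    order = np.argsort(-t, kind="stable")
    truth = {
        "clean_scores": t,
        "ranking": [(genes[iu[o]], genes[ju[o]]) for o in order],
        "informative_dims": spec.resolved_informative_dims(),
    }
    return scores, truth


def generate_ppi(spec: FixtureSpec, signatures: pd.DataFrame | None = None):
    """Stochastic-block-model PPI edge list with scores in [0, 1].

    Communities follow the dominant latent factor of the SL rule when
    signatures are supplied, otherwise a random balanced assignment. Returns
    ``(edges, communities)``.
    """
    rng = np.random.default_rng([spec.seed, 4])
    genes = spec.gene_names()
    if signatures is not None:
        comm = np.argmax(_latent_embedding(spec, signatures), axis=1)
    else:
        comm = rng.integers(0, spec.k_latent, size=spec.n_genes)
    rows = []
    for i in range(spec.n_genes):
        for j in range(i + 1, spec.n_genes):
            same = comm[i] == comm[j]
            if rng.random() < (0.35 if same else 0.03):
                score = rng.uniform(0.6, 1.0) if same else rng.uniform(0.2, 0.9)
                rows.append((genes[i], genes[j], round(float(score), 4)))
    edges = pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"])
    return edges, dict(zip(genes, (int(c) for c in comm)))


def generate_fixture(spec: FixtureSpec) -> dict:
    """Run all three generators plus the signature pipeline; bundle everything."""
    expression, metadata, plate_truth = generate_l1000_plates(spec)
    profiles = profiles_from_frames(expression, metadata)
    signatures = signatures_to_frame(build_gene_signatures(profiles),
                                     landmarks=expression.index)
    scores, score_truth = generate_sl_scores(spec, signatures)
    ppi, communities = generate_ppi(spec, signatures)
    return {
        "spec": spec,
        "expression": expression,
        "metadata": metadata,
        "signatures": signatures,
        "scores": scores,
        "ppi": ppi,
        "communities": communities,
        "planted_shifts": plate_truth["shifts"],
        "clean_scores": score_truth["clean_scores"],
        "ranking": score_truth["ranking"],
        "informative_dims": score_truth["informative_dims"],
    }


def write_fixture(bundle: dict, outdir) -> None:
    """Emit the fixture as GCT + TSVs + a ground-truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    eio.write_gct(bundle["expression"], out / "expression.gct")
    bundle["metadata"].to_csv(out / "metadata.tsv", sep="\t", index=False)
    (out / "landmarks.txt").write_text("\n".join(bundle["expression"].index) + "\n")
    eio.write_signatures(bundle["signatures"], out / "signatures.tsv")
    bundle["scores"].to_csv(out / "scores.tsv", sep="\t", index=False)
    bundle["ppi"].to_csv(out / "ppi.tsv", sep="\t", index=False)
    truth = {
        "spec": asdict(bundle["spec"]),
        "informative_dims": [int(d) for d in bundle["informative_dims"]],
        "communities": bundle["communities"],
        "planted_shifts": {g: [float(v) for v in row]
                           for g, row in bundle["planted_shifts"].iterrows()},
        "true_ranking": [list(p) for p in bundle["ranking"]],
    }
    (out / "truth.json").write_text(json.dumps(truth))
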