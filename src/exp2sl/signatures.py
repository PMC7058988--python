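"""L1000 signature construction: plate-wise robust z-scoring and replicate collapse.

Level-3 quantile-normalized shRNA profiles are referenced against the
empty-vector controls of the same plate,

    z_k = (x_k - median(V_k)) / (1.4826 * MAD(V_k)),

where V is the set of control profiles and 1.4826 scales the median absolute
deviation to a normal standard deviation. Replicates of one shRNA, and then
the shRNAs targeting one gene, are collapsed by a Spearman-weighted average
(MODZ-style), yielding one 978-dimensional z-score signature per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # consistency factor: scaled MAD estimates a normal sigma


@dataclass
class RawProfile:
    """One Level-3 expression profile plus the metadata the pipeline filters on."""

    sample_id: str
    values: np.ndarray
    plate_id: str
    pert_type: str  # "shRNA" or "vector_control"
    target_gene: str | None = None
    shrna_id: str | None = None
    timepoint_h: int = 96

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.pert_type == "vector_control" and self.target_gene:
            raise ValueError(f"control sample {self.sample_id} must not carry a target gene")


@dataclass
class ZScoreProfile:
    values: np.ndarray
    shrna_id: str
    target_gene: str
    plate_id: str


@dataclass
class GeneSignature:
    gene: str
    values: np.ndarray
    n_shrnas: int = 1
    n_profiles: int = 1


def robust_zscore(
    x: RawProfile,
    controls: list[RawProfile],
    mad_floor: float = 0.01,
    z_clip: float = 10.0,
) -> ZScoreProfile:
    """Robust z-score of a perturbed profile against same-plate controls.

    The scaled MAD (1.4826 * MAD) is floored at ``mad_floor`` so degenerate
    plates with constant controls cannot produce infinite z-scores, and the
    result is clipped to ``+-z_clip``.
    """
    if not controls:
        raise ValueError(f"no vector-control profiles available for plate {x.plate_id!r}")
    v = np.stack([c.values for c in controls])
    if v.shape[1] != x.values.shape[0]:
        raise ValueError(
            f"control profile length {v.shape[1]} != sample length {x.values.shape[0]}"
        )
    for c in controls:
        if c.plate_id != x.plate_id:
            raise ValueError(
                f"control {c.sample_id} is from plate {c.plate_id!r}, sample from {x.plate_id!r}"
            )
    med = np.median(v, axis=0)
    mad = np.median(np.abs(v - med), axis=0)
    scale = np.maximum(MAD_SCALE * mad, mad_floor)
    z = np.clip((x.values - med) / scale, -z_clip, z_clip)
    return ZScoreProfile(values=z, shrna_id=x.shrna_id, target_gene=x.target_gene,
                         plate_id=x.plate_id)


def collapse_weighted(vectors, weight_floor: float = 0.01) -> np.ndarray:
    """MODZ-style collapse: Spearman-correlation-weighted average of replicates.

    Weight of replicate i is the sum of its Spearman correlations with every
    other replicate, floored at ``weight_floor`` before normalizing to sum 1.
    A single vector is returned unchanged; two vectors reduce exactly to their
    arithmetic mean (the pairwise correlation is symmetric).
    """
    mat = np.stack([np.asarray(v, dtype=float) for v in vectors])
    n = mat.shape[0]
    if n == 0:
        raise ValueError("cannot collapse an empty replicate set")
    if n == 1:
        return mat[0].copy()
    ranks = np.apply_along_axis(rankdata, 1, mat)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1)
    norms[norms == 0] = 1.0  # constant vector: correlation contributes 0
    unit = ranks / norms[:, None]
    corr = unit @ unit.T
    np.fill_diagonal(corr, 0.0)
    w = np.maximum(corr.sum(axis=1), weight_floor)
    w /= w.sum()
    return w @ mat


def build_gene_signatures(
    profiles: list[RawProfile],
    timepoint_h: int = 96,
    mad_floor: float = 0.01,
    z_clip: float = 10.0,
) -> list[GeneSignature]:
    """Full pipeline: timepoint filter -> per-plate robust z -> two-stage collapse.

    Replicates of one shRNA are collapsed first, then the per-shRNA signatures
    of one gene, producing one signature per target gene. Genes left with no
    usable profile are dropped with a warning.
    """
    controls_by_plate: dict[str, list[RawProfile]] = {}
    for p in profiles:
        if p.pert_type == "vector_control":
            controls_by_plate.setdefault(p.plate_id, []).append(p)

    by_gene: dict[str, dict[str, list[ZScoreProfile]]] = {}
    for p in profiles:
        if p.pert_type != "shRNA" or p.timepoint_h != timepoint_h:
            continue
        controls = controls_by_plate.get(p.plate_id, [])
        z = robust_zscore(p, controls, mad_floor=mad_floor, z_clip=z_clip)
        by_gene.setdefault(p.target_gene, {}).setdefault(p.shrna_id, []).append(z)

    out = []
    for gene in sorted(by_gene):
        shrna_groups = by_gene[gene]
        per_shrna = [
            collapse_weighted([z.values for z in reps]) for _, reps in sorted(shrna_groups.items())
        ]
        if not per_shrna:
            logger.warning("gene %s has no surviving profiles; omitted", gene)
            continue
        values = collapse_weighted(per_shrna)
        n_profiles = sum(len(reps) for reps in shrna_groups.values())
        out.append(GeneSignature(gene=gene, values=values, n_shrnas=len(per_shrna),
                                 n_profiles=n_profiles))
    return out


def profiles_from_frames(expression: pd.DataFrame, metadata: pd.DataFrame) -> list[RawProfile]:
    """Pair a genes x samples expression matrix with its sample-metadata table."""
    profiles = []
    for row in metadata.itertuples(index=False):
        if row.sample_id not in expression.columns:
            raise KeyError(f"sample {row.sample_id!r} absent from expression matrix")
        target = None if pd.isna(row.target_gene) else str(row.target_gene)
        shrna = None if pd.isna(row.shrna_id) else str(row.shrna_id)
        profiles.append(
            RawProfile(
                sample_id=str(row.sample_id),
                values=expression[row.sample_id].to_numpy(dtype=float),
                plate_id=str(row.plate_id),
                pert_type=str(row.pert_type),
                target_gene=target,
                shrna_id=shrna,
                timepoint_h=int(row.timepoint_h),
            )
        )
    return profiles


def signatures_to_frame(signatures: list[GeneSignature], landmarks=None) -> pd.DataFrame:
    """Stack GeneSignatures into the interchange DataFrame (genes x landmarks)."""
    if not signatures:
        return pd.DataFrame()
    n = signatures[0].values.shape[0]
    cols = list(landmarks) if landmarks is not None else [f"L{i:03d}" for i in range(n)]
    data = np.stack([s.values for s in signatures])
    return pd.DataFrame(data, index=[s.gene for s in signatures], columns=cols)
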