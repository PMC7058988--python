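"""Readers and writers for the tabular formats the pipeline exchanges.

Expression matrices travel as GCT 1.3 text or GCTX (HDF5); everything else
(sample metadata, gene signatures, pair scores, labels, PPI edges) is plain
TSV read with pandas.
"""

from __future__ import annotations

import pandas as pd

META_COLUMNS = ["sample_id", "plate_id", "pert_type", "target_gene", "shrna_id", "timepoint_h"]


def read_gct(path) -> pd.DataFrame:
    """Read a GCT 1.3 text matrix into a genes x samples DataFrame.

    Row/column metadata fields beyond the identifiers are parsed and dropped;
    only the numeric data block is returned, indexed by row id with sample ids
    as columns.
    """
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.3", "#1.2"):
            raise ValueError(f"unsupported GCT version line: {version!r}")
        dims = fh.readline().split()
        if version == "#1.2":
            nrow, ncol = int(dims[0]), int(dims[1])
            nrhd, nchd = 0, 0
            offset = 2  # id + Description columns
        else:
            nrow, ncol, nrhd, nchd = (int(d) for d in dims[:4])
            offset = 1 + nrhd
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[offset:]
        # skip column-metadata rows
        for _ in range(nchd):
            fh.readline()
        ids, rows = [], []
        for _ in range(nrow):
            parts = fh.readline().rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[offset:]])
    if len(sample_ids) != ncol:
        raise ValueError(f"GCT header declares {ncol} samples, found {len(sample_ids)}")
    return pd.DataFrame(rows, index=ids, columns=sample_ids)


def write_gct(df: pd.DataFrame, path) -> None:
    """Write a genes x samples DataFrame as GCT 1.3 with no metadata fields."""
    with open(path, "w") as fh:
        fh.write("#1.3\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\t0\t0\n")
        fh.write("id\t" + "\t".join(map(str, df.columns)) + "\n")
        for rid, row in zip(df.index, df.to_numpy()):
            fh.write(str(rid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_gctx(path) -> pd.DataFrame:
    """Read a GCTX (HDF5) matrix into a genes x samples DataFrame."""
    import h5py

    with h5py.File(path, "r") as fh:
        mat = fh["0/DATA/0/matrix"][()]
        rids = [r.decode() if isinstance(r, bytes) else str(r) for r in fh["0/META/ROW/id"][()]]
        cids = [c.decode() if isinstance(c, bytes) else str(c) for c in fh["0/META/COL/id"][()]]
    # GCTX stores the matrix samples x genes
    if mat.shape == (len(cids), len(rids)):
        mat = mat.T
    return pd.DataFrame(mat, index=rids, columns=cids)


def read_expression(path) -> pd.DataFrame:
    """Dispatch on extension: .gctx -> HDF5, anything else -> GCT text."""
    if str(path).endswith(".gctx"):
        return read_gctx(path)
    return read_gct(path)


def read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "plate_id": str})
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns: {missing}")
    return meta


def read_landmarks(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_signatures(path) -> pd.DataFrame:
    """Gene-signature TSV: rows = genes, named landmark columns."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_signatures(signatures: pd.DataFrame, path) -> None:
    signatures.to_csv(path, sep="\t", index_label="gene")


def read_pair_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"pair-score table needs columns {sorted(required)}")
    return df


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_a", "gene_b", "label"}.issubset(df.columns):
        raise ValueError("label table needs columns gene_a, gene_b, label")
    return df


def write_labels(pairs_pos, pairs_neg, path) -> None:
    rows = [(a, b, 1) for a, b in sorted(pairs_pos)] + [(a, b, -1) for a, b in sorted(pairs_neg)]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "label"]).to_csv(path, sep="\t", index=False)


def read_ppi_edges(path) -> pd.DataFrame:
    """STRING-style edge list: protein_a, protein_b, combined_score.

    Scores on the 0..1000 convention are rescaled to [0, 1].
    """
    df = pd.read_csv(path, sep="\t")
    if not {"protein_a", "protein_b", "combined_score"}.issubset(df.columns):
        raise ValueError("PPI table needs columns protein_a, protein_b, combined_score")
    if (df["combined_score"] > 1).any():
        df = df.assign(combined_score=df["combined_score"] / 1000.0)
    return df


def write_similarity(sim, path) -> None:
    sim.to_frame().to_csv(path, sep="\t", index_label="gene")
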