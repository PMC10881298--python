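"""Reading and writing the pipeline's on-disk formats.

Feature tables travel as GFF3 (1-based inclusive coordinates, attributes
``ID``, ``gene_label``, and optionally ``mag_id`` / ``fp_override``);
abundance matrices as TSV with a JSON sidecar (``<path>.meta.json``)
recording the normalization state, marker set, per-feature lengths and
labels, and per-sample mapped reads, so a matrix can be round-tripped
without losing its provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .abundance import AbundanceMatrix

GFF_SOURCE = "b1cycle"


def write_gff3(features: pd.DataFrame, path) -> None:
    """Write a feature table as GFF3."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for row in features.itertuples(index=False):
            attrs = [f"ID={row.feature_id}", f"gene_label={row.gene_label}"]
            if hasattr(row, "mag_id"):
                attrs.append(f"mag_id={row.mag_id}")
            if hasattr(row, "fp_override"):
                attrs.append(f"fp_override={'true' if row.fp_override else 'false'}")
            ftype = "riboswitch" if row.gene_label == "riboswitch_TDP" else "gene"
            fh.write(
                "\t".join(
                    [
                        str(row.contig_id), GFF_SOURCE, ftype,
                        str(int(row.start)), str(int(row.end)), ".",
                        str(row.strand), ".", ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> pd.DataFrame:
    """Read a GFF3 feature file back into a feature table."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for f in db.all_features():
        rows.append(
            {
                "contig_id": f.seqid,
                "feature_id": f.attributes.get("ID", [f.id])[0],
                "gene_label": f.attributes.get("gene_label", [f.featuretype])[0],
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "length": f.end - f.start + 1,
                "mag_id": f.attributes.get("mag_id", [""])[0],
                "fp_override": f.attributes.get("fp_override", ["false"])[0] == "true",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["contig_id", "feature_id", "gene_label", "start", "end",
                 "strand", "length", "mag_id", "fp_override"],
    )


def write_matrix(matrix: AbundanceMatrix, path) -> None:
    """Write values as TSV plus a ``<path>.meta.json`` sidecar."""
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")
    meta = {
        "state": matrix.state,
        "marker_ids": list(matrix.marker_ids),
        "gene_lengths": (
            matrix.gene_lengths.to_dict() if matrix.gene_lengths is not None else None
        ),
        "mapped_reads": (
            matrix.mapped_reads.to_dict() if matrix.mapped_reads is not None else None
        ),
        "feature_meta": (
            matrix.feature_meta.to_dict(orient="index")
            if matrix.feature_meta is not None
            else None
        ),
        "mode": matrix.meta.get("mode"),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_matrix(path) -> AbundanceMatrix:
    """Round-trip counterpart of :func:`write_matrix`."""
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="feature_id")
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    feature_meta = None
    if meta.get("feature_meta") is not None:
        feature_meta = pd.DataFrame.from_dict(meta["feature_meta"], orient="index")
    return AbundanceMatrix(
        values=values,
        state=meta["state"],
        gene_lengths=pd.Series(meta["gene_lengths"]) if meta.get("gene_lengths") else None,
        mapped_reads=pd.Series(meta["mapped_reads"]) if meta.get("mapped_reads") else None,
        marker_ids=tuple(meta.get("marker_ids") or ()),
        feature_meta=feature_meta,
        meta={"mode": meta.get("mode")} if meta.get("mode") else {},
    )
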