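"""Readers and writers for the pipeline's on-disk formats.

Feature tables travel as TSV (samples in rows, taxon IDs in the header) or
as BIOM v1 JSON; metadata as CSV; clique definitions and ground truth as
JSON sidecars.  The BIOM support covers the v1 (JSON) subset needed for
round-tripping dense/sparse sample x observation tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GroundTruth, PlantedClique
from .discovery import Clique
from .prep import FeatureTable


# --- feature tables ---------------------------------------------------------


def write_table_tsv(table: FeatureTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_table_tsv(path) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FeatureTable(df)


def write_table_biom(table: FeatureTable, path) -> None:
    """Write BIOM v1 JSON (sparse, observations x samples as BIOM mandates)."""
    df = table.data
    vals = df.to_numpy()
    rows_obs, cols_smp = np.nonzero(vals.T)
    data = [
        [int(r), int(c), float(vals[c, r])] for r, c in zip(rows_obs, cols_smp)
    ]
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "mica",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "float",
        "shape": [df.shape[1], df.shape[0]],
        "rows": [
            {
                "id": t,
                "metadata": (
                    {"taxonomy": table.taxon_labels[t]}
                    if table.taxon_labels and t in table.taxon_labels
                    else None
                ),
            }
            for t in df.columns
        ],
        "columns": [{"id": s, "metadata": None} for s in df.index],
        "data": data,
    }
    Path(path).write_text(json.dumps(doc))


def read_table_biom(path) -> FeatureTable:
    doc = json.loads(Path(path).read_text())
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(samples), len(taxa)))
    if doc["matrix_type"] == "sparse":
        for r, c, v in doc["data"]:
            mat[c, r] = v
    else:
        mat = np.asarray(doc["data"], dtype=float).T
    labels = {
        r["id"]: r["metadata"]["taxonomy"]
        for r in doc["rows"]
        if r.get("metadata") and "taxonomy" in r["metadata"]
    }
    return FeatureTable(pd.DataFrame(mat, index=samples, columns=taxa),
                        labels or None)


# --- metadata ---------------------------------------------------------------


def write_metadata_csv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index_label="sample_id")


def read_metadata_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


# --- ground truth sidecar ---------------------------------------------------


def write_ground_truth(truth: GroundTruth, path) -> None:
    doc = {
        "cliques": [
            {
                "taxa_indices": list(cl.taxa),
                "taxa_ids": list(ids),
                "effect_secure": cl.effect_secure,
                "effect_insecure": cl.effect_insecure,
                "joint": cl.joint,
            }
            for cl, ids in zip(truth.cliques, truth.clique_taxa)
        ],
        "latent": truth.latent.tolist(),
        "score_cutpoints": truth.score_cutpoints.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def read_ground_truth(path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    cliques = [
        PlantedClique(
            taxa=tuple(c["taxa_indices"]),
            effect_secure=c["effect_secure"],
            effect_insecure=c["effect_insecure"],
            joint=c["joint"],
        )
        for c in doc["cliques"]
    ]
    return GroundTruth(
        cliques=cliques,
        clique_taxa=[tuple(c["taxa_ids"]) for c in doc["cliques"]],
        coefficients=[
            {"secure": c["effect_secure"], "insecure": c["effect_insecure"]}
            for c in doc["cliques"]
        ],
        latent=np.asarray(doc["latent"]),
        score_cutpoints=np.asarray(doc["score_cutpoints"]),
    )


# --- clique definitions -----------------------------------------------------


def write_cliques(cliques: list, path) -> None:
    doc = [
        {"taxa": list(cl.taxa), "stability": cl.stability} for cl in cliques
    ]
    Path(path).write_text(json.dumps(doc, indent=1))


def read_cliques(path) -> list:
    doc = json.loads(Path(path).read_text())
    return [
        Clique(taxa=tuple(c["taxa"]), stability=float(c.get("stability", 1.0)))
        for c in doc
    ]
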