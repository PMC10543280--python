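"""Serialisation of simulation results and ground truths.

Count-like matrices are written as MatrixMarket (MTX) with row/column name
sidecars; signed real matrices (velocity) and all tables go to TSV with
headers.  A manifest with SHA-256 checksums covers every written file, and a
config echo (YAML) allows byte-identical re-runs given the same seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .core import SimConfig, load_grn, load_lr_database, parse_tree

__all__ = ["write_bundle", "read_matrix", "config_to_yaml", "config_from_yaml"]


def _write_mtx(path: Path, matrix: np.ndarray, prefix: str) -> list[Path]:
    m = sparse.csr_matrix(np.asarray(matrix))
    spio.mmwrite(str(path), m)
    ncell, ncol = matrix.shape
    rows = path.parent / f"{prefix}.rows.tsv"
    cols = path.parent / f"{prefix}.cols.tsv"
    rows.write_text("\n".join(f"cell{i}" for i in range(1, ncell + 1)) + "\n")
    cols.write_text("\n".join(f"{prefix.split('_')[0]}{j}"
                              for j in range(1, ncol + 1)) + "\n")
    return [path, rows, cols]


def read_matrix(path) -> np.ndarray:
    """Read back a matrix written by :func:`write_bundle` (MTX or TSV)."""
    path = Path(path)
    if path.suffix == ".mtx":
        return np.asarray(spio.mmread(str(path)).todense())
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy()


def write_bundle(result, out_dir, dense: bool = False) -> dict:
    """Write a full output bundle; returns the manifest (also saved).

    Layout: ``counts_rna.mtx`` (+ observed if present in ``extras``),
    ``counts_atac.mtx``, ``unspliced.mtx``/``velocity.tsv`` in velocity mode,
    ``cell_meta.tsv``, ``grn_truth.tsv``, ``region_to_gene.tsv``,
    ``cci_type_truth.tsv``/``cci_cell_truth.tsv``, ``config.yaml`` and
    ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        written += _write_mtx(out / "counts_rna.mtx", result.counts, "gene_rna")
        if dense:
            pd.DataFrame(result.counts).to_csv(out / "counts_rna.tsv", sep="\t")
            written.append(out / "counts_rna.tsv")
        if result.atac is not None:
            written += _write_mtx(out / "counts_atac.mtx",
                                  result.atac.accessibility, "region_atac")
            r, g = np.nonzero(result.atac.region_to_gene)
            pd.DataFrame({"region": r + 1, "gene": g + 1}).to_csv(
                out / "region_to_gene.tsv", sep="\t", index=False)
            written.append(out / "region_to_gene.tsv")
        if result.unspliced is not None:
            written += _write_mtx(out / "unspliced.mtx", result.unspliced,
                                  "gene_unspliced")
        if result.velocity is not None:
            pd.DataFrame(result.velocity).to_csv(out / "velocity.tsv", sep="\t")
            written.append(out / "velocity.tsv")
        meta = result.cell_meta_frame()
        meta.to_csv(out / "cell_meta.tsv", sep="\t", index=False)
        written.append(out / "cell_meta.tsv")
        if result.config.grn is not None:
            result.config.grn.edges.to_csv(out / "grn_truth.tsv", sep="\t",
                                           index=False)
            written.append(out / "grn_truth.tsv")
        if result.cci_truth is not None:
            result.cci_truth.type_frame().to_csv(out / "cci_type_truth.tsv",
                                                 sep="\t", index=False)
            result.cci_truth.cell_frame().to_csv(out / "cci_cell_truth.tsv",
                                                 sep="\t", index=False)
            written += [out / "cci_type_truth.tsv", out / "cci_cell_truth.tsv"]
        (out / "config.yaml").write_text(config_to_yaml(result.config))
        written.append(out / "config.yaml")
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    manifest = {
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in written
        }
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def config_to_yaml(config: SimConfig) -> str:
    data = {}
    for key, val in vars(config).items():
        if key == "tree":
            data["tree"] = val.to_newick()
        elif key == "grn":
            data["grn"] = None if val is None else \
                val.edges.to_dict(orient="records")
        elif key == "lr_db":
            data["lr_db"] = None if val is None else \
                val.rows.to_dict(orient="records")
        elif isinstance(val, tuple):
            data[key] = list(val)
        else:
            data[key] = val
    return yaml.safe_dump(data, sort_keys=True)


def config_from_yaml(text: str) -> SimConfig:
    data = yaml.safe_load(text)
    kwargs = dict(data)
    kwargs["tree"] = parse_tree(data["tree"])
    ngene = int(data.get("ngene", 100))
    if data.get("grn"):
        kwargs["grn"] = load_grn(
            [(r["regulator"], r["target"], r["effect"]) for r in data["grn"]],
            ngene)
    else:
        kwargs["grn"] = None
    if data.get("lr_db"):
        kwargs["lr_db"] = load_lr_database(
            [(r["ligand"], r["receptor"], r["effect"]) for r in data["lr_db"]])
    else:
        kwargs["lr_db"] = None
    for key in ("region_dist", "lr_pairs_range"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return SimConfig(**kwargs)
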