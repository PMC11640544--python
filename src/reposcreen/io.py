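"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as TSV (first column the feature id, header the
sample ids) or GCT 1.2; drug-response tables and subtype labels as TSV;
fitted model bundles as a directory holding a YAML manifest plus one
coefficient TSV per drug.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .imputation import (DrugModel, PowerTransformParams, RidgeFit,
                         RidgeModelBundle)

# --- expression matrices ---------------------------------------------------


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label=expr.index.name or "gene")


def read_gct(path) -> pd.DataFrame:
    """Read a GCT 1.2 expression matrix (Description column dropped)."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"unsupported GCT version line {version!r}")
        fh.readline()  # dimensions line; pandas infers the rest
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"], errors="ignore")
    df.index.name = "gene"
    return df


def write_gct(expr: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{expr.shape[0]}\t{expr.shape[1]}\n")
        out = expr.copy()
        out.insert(0, "Description", "na")
        out.to_csv(fh, sep="\t", index_label="Name")


# --- small tables ----------------------------------------------------------


def read_probe_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    missing = {"probe_id", "gene_symbol"} - set(ann.columns)
    if missing:
        raise ValueError(f"annotation lacks column(s): {sorted(missing)}")
    return ann[["probe_id", "gene_symbol"]]


def read_drug_response(path) -> pd.DataFrame:
    """Cell lines x drugs AUC table (first column the cell-line id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("group").to_csv(path, sep="\t",
                                  index_label=labels.index.name or "sample_id")


_DE_ALIASES = {
    "log2foldchange": "log2FC", "lfc": "log2FC", "log2fc": "log2FC",
    "p_value": "pvalue", "p": "pvalue", "pval": "pvalue", "pvalue": "pvalue",
    "p_adj": "padj", "fdr": "padj", "qvalue": "padj", "padj": "padj",
    "gene": "gene", "gene_symbol": "gene",
}


def read_de_table(path) -> pd.DataFrame:
    """Read a DE result table, normalizing common column-name variants."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={c: _DE_ALIASES.get(c.lower(), c) for c in df.columns})
    missing = {"gene", "log2FC", "padj"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table lacks column(s): {sorted(missing)}")
    return df


# --- model bundles ---------------------------------------------------------


def save_bundle(bundle: RidgeModelBundle, dirpath) -> None:
    """Serialize a bundle: manifest.yaml + coefficients/<drug>.tsv."""
    root = Path(dirpath)
    (root / "coefficients").mkdir(parents=True, exist_ok=True)
    manifest = {"format": "reposcreen-bundle-1", "genes": bundle.genes,
                "skipped": dict(bundle.skipped), "drugs": {}}
    for drug, model in bundle.models.items():
        fit = model.fit
        tsv = f"coefficients/{drug}.tsv"
        pd.DataFrame({
            "gene": model.genes,
            "beta": fit.beta,
            "mean": fit.gene_means,
            "sd": fit.gene_sds,
        }).to_csv(root / tsv, sep="\t", index=False)
        entry = {"intercept": float(fit.intercept), "lambda": float(fit.lam),
                 "n_lines": model.n_lines, "coefficients": tsv,
                 "transform": None}
        if model.transform is not None:
            entry["transform"] = {"family": model.transform.family,
                                  "lam": float(model.transform.lam),
                                  "shift": float(model.transform.shift)}
        manifest["drugs"][drug] = entry
    with open(root / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def load_bundle(dirpath) -> RidgeModelBundle:
    root = Path(dirpath)
    with open(root / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    if manifest.get("format") != "reposcreen-bundle-1":
        raise ValueError("not a reposcreen model bundle")
    models: dict[str, DrugModel] = {}
    for drug, entry in manifest["drugs"].items():
        coefs = pd.read_csv(root / entry["coefficients"], sep="\t")
        transform = None
        if entry["transform"] is not None:
            t = entry["transform"]
            transform = PowerTransformParams(lam=t["lam"], shift=t["shift"],
                                             family=t["family"])
        fit = RidgeFit(beta=coefs["beta"].values.astype(float),
                       intercept=float(entry["intercept"]),
                       gene_means=coefs["mean"].values.astype(float),
                       gene_sds=coefs["sd"].values.astype(float),
                       lam=float(entry["lambda"]))
        models[drug] = DrugModel(fit=fit, transform=transform,
                                 genes=list(coefs["gene"]),
                                 n_lines=int(entry["n_lines"]))
    return RidgeModelBundle(models=models, genes=list(manifest["genes"]),
                            skipped=dict(manifest.get("skipped", {})))
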