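"""Readers/writers for the package's on-disk dialects.

Matrices are TSV with samples as rows and a header of feature ids; feature
annotations are GMT (set name, description, then tab-separated members);
patch tables and TIL maps are TSV keyed by slide id and 0-based grid
coordinates; survival records are TSV (sample_id, time_days, event). Graphs
serialise to HDF5; model weights to a single .npz checkpoint carrying a JSON
config echo. Every written directory gets a manifest with file digests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .omics import FeatureAnnotation
from .survival import SurvivalData
from .wsg import PatchSet, WholeSlideGraph

__all__ = [
    "write_matrix_tsv", "read_matrix_tsv", "write_gmt", "read_gmt",
    "write_patches_tsv", "read_patches_tsv", "write_survival_tsv",
    "read_survival_tsv", "write_til_tsv", "read_til_tsv",
    "write_cohort", "read_cohort_inputs", "write_graph_h5", "read_graph_h5",
    "save_checkpoint", "load_checkpoint", "write_manifest", "file_digest",
]


def write_matrix_tsv(path, matrix: np.ndarray, sample_ids, feature_ids) -> None:
    df = pd.DataFrame(matrix, index=sample_ids, columns=feature_ids)
    # %.17g round-trips float64 exactly
    df.to_csv(path, sep="\t", index_label="sample_id", float_format="%.17g")


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=np.float64), list(df.index.astype(str)), list(df.columns)


def write_gmt(path, annotation: FeatureAnnotation) -> None:
    groups: dict[str, list[str]] = {c: [] for c in annotation.capsule_order}
    for f, c in annotation.entries:
        groups[c].append(f)
    with open(path, "w") as fh:
        for name, members in groups.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_gmt(path) -> FeatureAnnotation:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    if not sets:
        raise ValueError(f"no sets parsed from {path}")
    return FeatureAnnotation.from_sets(sets)


def write_patches_tsv(path, slides: list[PatchSet]) -> None:
    rows = []
    for ps in slides:
        for (r, c), emb in zip(ps.coords, ps.embeddings):
            rows.append([ps.slide_id, int(r), int(c), *emb])
    d = slides[0].embeddings.shape[1]
    cols = ["slide_id", "row", "col"] + [f"e_{j + 1}" for j in range(d)]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False,
                                            float_format="%.17g")


def read_patches_tsv(path) -> list[PatchSet]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    emb_cols = [c for c in df.columns if c.startswith("e_")]
    slides = []
    for sid, grp in df.groupby("slide_id", sort=False):
        slides.append(PatchSet(slide_id=str(sid),
                               coords=grp[["row", "col"]].to_numpy(dtype=float),
                               embeddings=grp[emb_cols].to_numpy(dtype=float)))
    return slides


def write_survival_tsv(path, surv: SurvivalData, sample_ids) -> None:
    pd.DataFrame({"sample_id": sample_ids, "time_days": surv.time,
                  "event": surv.event}).to_csv(path, sep="\t", index=False,
                                               float_format="%.17g")


def read_survival_tsv(path) -> tuple[list[str], SurvivalData]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return (list(df["sample_id"].astype(str)),
            SurvivalData(df["time_days"].to_numpy(float), df["event"].to_numpy(int)))


def write_til_tsv(path, slides: list[PatchSet], til_masks: list[np.ndarray]) -> None:
    rows = []
    for ps, mask in zip(slides, til_masks):
        n_main = len(mask)
        for (r, c), t in zip(ps.coords[:n_main], np.asarray(mask, dtype=int)):
            rows.append([ps.slide_id, int(r), int(c), int(t)])
    pd.DataFrame(rows, columns=["slide_id", "row", "col", "til"]).to_csv(
        path, sep="\t", index=False)


def read_til_tsv(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return {str(sid): grp[["row", "col", "til"]].to_numpy(int)
            for sid, grp in df.groupby("slide_id", sort=False)}


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(outdir: Path, config_echo: dict, seeds: dict, files: list[str]) -> dict:
    from . import __version__
    outdir = Path(outdir)
    manifest = {
        "package_version": __version__,
        "config": config_echo,
        "seeds": seeds,
        "outputs": {f: file_digest(outdir / f) for f in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def write_cohort(cohort, outdir) -> dict:
    """Write a synthetic cohort in the package's TSV/GMT dialects + manifest."""
    from dataclasses import asdict
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample_ids = [f"P{i:04d}" for i in range(len(cohort))]
    write_matrix_tsv(outdir / "expression.tsv", cohort.expression, sample_ids,
                     cohort.gene_ids)
    write_matrix_tsv(outdir / "methylation.tsv", cohort.methylation, sample_ids,
                     cohort.cpg_ids)
    write_gmt(outdir / "pathways.gmt", cohort.pathway_annotation)
    write_gmt(outdir / "cpg2gene.gmt", cohort.cpg_annotation)
    write_patches_tsv(outdir / "patches.tsv", cohort.slides)
    write_survival_tsv(outdir / "survival.tsv", cohort.survival, sample_ids)
    write_til_tsv(outdir / "til.tsv", cohort.slides, cohort.truth.til_masks)
    files = ["expression.tsv", "methylation.tsv", "pathways.gmt", "cpg2gene.gmt",
             "patches.tsv", "survival.tsv", "til.tsv"]
    return write_manifest(outdir, asdict(cohort.config), {"seed": cohort.config.seed}, files)


def read_cohort_inputs(indir) -> dict:
    """Read the cohort dialect back into in-memory containers."""
    indir = Path(indir)
    expr, sample_ids, gene_ids = read_matrix_tsv(indir / "expression.tsv")
    meth, _, cpg_ids = read_matrix_tsv(indir / "methylation.tsv")
    sids, surv = read_survival_tsv(indir / "survival.tsv")
    return {
        "expression": expr, "methylation": meth,
        "sample_ids": sample_ids, "gene_ids": gene_ids, "cpg_ids": cpg_ids,
        "pathway_annotation": read_gmt(indir / "pathways.gmt"),
        "cpg_annotation": read_gmt(indir / "cpg2gene.gmt"),
        "slides": read_patches_tsv(indir / "patches.tsv"),
        "survival": surv,
        "til": read_til_tsv(indir / "til.tsv") if (indir / "til.tsv").exists() else None,
    }


def write_graph_h5(path, wsg: WholeSlideGraph) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["slide_id"] = wsg.slide_id
        f.create_dataset("coords", data=wsg.coords)
        f.create_dataset("features", data=wsg.features)
        f.create_dataset("edges", data=wsg.edges)
        f.create_dataset("orig_index", data=wsg.orig_index)


def read_graph_h5(path) -> WholeSlideGraph:
    with h5py.File(path, "r") as f:
        return WholeSlideGraph(
            slide_id=str(f.attrs["slide_id"]),
            coords=f["coords"][...], features=f["features"][...],
            edges=f["edges"][...].astype(np.intp),
            orig_index=f["orig_index"][...].astype(np.intp))


def save_checkpoint(path, model, config_echo: dict) -> None:
    arrays = {f"param_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __config__=np.frombuffer(
        json.dumps(config_echo, default=str).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, model) -> dict:
    with np.load(path) as z:
        keys = sorted(k for k in z.files if k.startswith("param_"))
        model.load_arrays([z[k] for k in keys])
        return json.loads(bytes(z["__config__"]).decode())
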