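"""Tab-delimited and JSON/YAML interfaces between pipeline stages.

Matrices are written samples-as-rows with a header of metabolite ids and
missing cells as empty fields; cell flags and sample metadata travel in
sidecar files. GWAS summary-statistics tables use the fixed header
``snp effect_allele other_allele eaf beta se pval n``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .mr import GWAS_COLUMNS, _validate_gwas
from .qc import MetaboliteMatrix, PanelSpec


def write_matrix(matrix: MetaboliteMatrix, prefix: str | Path) -> list[Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = [prefix.with_suffix(".values.tsv"), prefix.with_suffix(".flags.tsv")]
    matrix.values.to_csv(paths[0], sep="\t", na_rep="")
    matrix.flags.to_csv(paths[1], sep="\t")
    if matrix.sample_meta is not None:
        p = prefix.with_suffix(".samples.tsv")
        matrix.sample_meta.to_csv(p, sep="\t")
        paths.append(p)
    return paths


def read_matrix(prefix: str | Path) -> MetaboliteMatrix:
    prefix = Path(prefix)
    values = pd.read_csv(prefix.with_suffix(".values.tsv"), sep="\t", index_col=0)
    flags_path = prefix.with_suffix(".flags.tsv")
    flags = (pd.read_csv(flags_path, sep="\t", index_col=0).astype("int8")
             if flags_path.exists() else None)
    samples_path = prefix.with_suffix(".samples.tsv")
    meta = (pd.read_csv(samples_path, sep="\t", index_col=0)
            if samples_path.exists() else None)
    return MetaboliteMatrix(values, flags, meta)


def write_panel(panel: PanelSpec, prefix: str | Path) -> list[Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = [prefix.with_suffix(".panel.tsv"), prefix.with_suffix(".limits.tsv")]
    panel.table.to_csv(paths[0], sep="\t")
    panel.limits.to_csv(paths[1], sep="\t", index=False)
    return paths


def read_panel(prefix: str | Path) -> PanelSpec:
    prefix = Path(prefix)
    table = pd.read_csv(prefix.with_suffix(".panel.tsv"), sep="\t", index_col=0)
    limits = pd.read_csv(prefix.with_suffix(".limits.tsv"), sep="\t")
    return PanelSpec(table, limits)


def write_gwas(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[list(GWAS_COLUMNS)].to_csv(path, sep="\t", index=False)
    return path


def read_gwas(path: str | Path) -> pd.DataFrame:
    return _validate_gwas(pd.read_csv(path, sep="\t"), str(path))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of sections")
    return cfg


def sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, stage: str, config: dict,
                   outputs: list[Path], seeds: dict | None = None) -> Path:
    """Stage run manifest: echoed config, output checksums, seeds."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "config": config,
        "seeds": seeds or {},
        "outputs": {str(p): sha256(p) for p in outputs},
    }
    path = out_dir / f"{stage}.manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
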