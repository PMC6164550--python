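"""Reading count tables, persisting posterior draws, and writing summaries.

The on-disk count-table dialect is a plain CSV with a header row:
``observation_id, depth_m`` followed by one integer column per category.
Posterior draws persist as a ``.npz`` archive plus a JSON sidecar holding
the basis, covariate standardisation, priors, sampler settings and
diagnostics, so predictions are reproducible from disk alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    CountTable,
    ModelSpec,
    PosteriorDraws,
    PriorSpec,
    SamplerSpec,
)
from .simplex import IlrBasis

__all__ = [
    "read_count_table",
    "write_count_table",
    "save_draws",
    "load_draws",
    "RunConfig",
    "write_summaries",
]

ID_COLUMN = "observation_id"
DEPTH_COLUMN = "depth_m"


def read_count_table(
    path, column_map: dict[str, str] | None = None
) -> CountTable:
    """Read a count table from CSV.

    ``column_map`` renames file columns to the expected names before
    validation (e.g. ``{"still": "observation_id", "depth": "depth_m"}``).
    Category column order in the file is irrelevant: labels travel with
    the table.  Malformed cells are rejected with row and column identity.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    for col in (ID_COLUMN, DEPTH_COLUMN):
        if col not in df.columns:
            raise ValueError(f"missing required column '{col}' in {path}")
    cat_cols = [c for c in df.columns if c not in (ID_COLUMN, DEPTH_COLUMN)]
    if not cat_cols:
        raise ValueError("no category columns found")
    bad = []
    for col in cat_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        mask = vals.isna() | (vals != vals.round()) | (vals < 0)
        for i in df.index[mask]:
            bad.append(f"row {df.loc[i, ID_COLUMN]!r}, column {col!r}")
    if bad:
        raise ValueError("non-integer or negative counts at: " + "; ".join(bad))
    counts = df[cat_cols].to_numpy(dtype=np.int64)
    zero_rows = np.flatnonzero(counts.sum(axis=1) == 0)
    if zero_rows.size:
        ids = [repr(df.iloc[i][ID_COLUMN]) for i in zero_rows]
        raise ValueError("rows with zero total counts: " + ", ".join(ids))
    return CountTable(
        counts,
        df[DEPTH_COLUMN].to_numpy(dtype=float),
        tuple(cat_cols),
        tuple(str(x) for x in df[ID_COLUMN]),
    )


def write_count_table(table: CountTable, path) -> None:
    ids = table.observation_ids or tuple(
        f"obs_{i:03d}" for i in range(table.n_obs)
    )
    df = pd.DataFrame(table.counts, columns=list(table.category_labels))
    df.insert(0, DEPTH_COLUMN, table.covariate)
    df.insert(0, ID_COLUMN, ids)
    df.to_csv(path, index=False)


def save_draws(draws: PosteriorDraws, prefix) -> None:
    """Persist draws to ``<prefix>.npz`` + ``<prefix>.json``."""
    prefix = Path(prefix)
    np.savez_compressed(
        prefix.with_suffix(".npz"),
        beta=draws.beta,
        chol=draws.chol,
        eps=draws.eps,
        z=draws.z,
        counts=draws.data.counts,
        covariate=draws.data.covariate,
        contrast_matrix=draws.basis.contrast_matrix,
    )
    meta = {
        "z_center": draws.z_center,
        "z_scale": draws.z_scale,
        "n_chains": draws.n_chains,
        "category_labels": list(draws.data.category_labels),
        "observation_ids": list(draws.data.observation_ids or []),
        "degree": draws.spec.degree,
        "priors": dataclasses.asdict(draws.spec.priors),
        "sampler": dataclasses.asdict(draws.spec.sampler),
        "diagnostics": draws.diagnostics,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_draws(prefix) -> PosteriorDraws:
    prefix = Path(prefix)
    arrays = np.load(prefix.with_suffix(".npz"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    labels = tuple(meta["category_labels"])
    basis = IlrBasis(arrays["contrast_matrix"], labels)
    data = CountTable(
        arrays["counts"],
        arrays["covariate"],
        labels,
        tuple(meta["observation_ids"]) or None,
    )
    spec = ModelSpec(
        degree=meta["degree"],
        basis=basis,
        priors=PriorSpec(**meta["priors"]),
        sampler=SamplerSpec(**meta["sampler"]),
    )
    return PosteriorDraws(
        beta=arrays["beta"],
        chol=arrays["chol"],
        eps=arrays["eps"],
        basis=basis,
        z=arrays["z"],
        z_center=meta["z_center"],
        z_scale=meta["z_scale"],
        data=data,
        spec=spec,
        n_chains=meta["n_chains"],
        diagnostics=meta["diagnostics"],
    )


_CONFIG_FIELDS = {
    "input": str,
    "output_dir": str,
    "merge_map": dict,
    "exclude": list,
    "degree": int,
    "beta_scale": float,
    "re_scale": float,
    "offdiag_scale": float,
    "chains": int,
    "warmup": int,
    "draws": int,
    "seed": int,
    "target_accept": float,
    "grid_size": int,
    "hpd_level": float,
}


@dataclasses.dataclass
class RunConfig:
    """One-file configuration of a pipeline run; unknown keys are rejected."""

    input: str = ""
    output_dir: str = "gradcoda_out"
    merge_map: dict | None = None
    exclude: list | None = None
    degree: int = 2
    beta_scale: float = 5.0
    re_scale: float = 2.0
    offdiag_scale: float = 1.0
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    target_accept: float = 0.9
    grid_size: int = 100
    hpd_level: float = 0.95

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(_CONFIG_FIELDS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            degree=self.degree,
            priors=PriorSpec(self.beta_scale, self.re_scale, self.offdiag_scale),
            sampler=SamplerSpec(
                chains=self.chains,
                warmup=self.warmup,
                draws=self.draws,
                seed=self.seed,
                target_accept=self.target_accept,
            ),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_summaries(outputs: dict[str, "pd.DataFrame"], outdir) -> dict:
    """Write tidy summary CSVs plus a manifest with checksums.

    ``outputs`` maps file stems to DataFrames.  Returns the manifest, which
    is also written as ``manifest.json`` in ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"files": []}
    for stem, df in outputs.items():
        path = outdir / f"{stem}.csv"
        df.to_csv(path, index=False)
        manifest["files"].append({"name": path.name, "sha256": _sha256(path)})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
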