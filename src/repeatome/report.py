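"""Genome-size accounting, composition tables and pipeline orchestration.

Conversions follow the flow-cytometry convention 1 pg = 0.978 Gbp; all
table rounding is half-up at the precision repeatome tables are
customarily printed at (3 decimals of Gbp, 2-3 decimals of coverage).
"""

from __future__ import annotations

import importlib.resources
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

PG_TO_GBP = 0.978


def _round_half_up(x: float, dp: int) -> float:
    scale = 10**dp
    return math.floor(x * scale + 0.5) / scale


def pg2C_to_gbp1C(size_2C_pg: float, ploidy: int = 2) -> tuple[float, float]:
    """(G_1C, G_1Cx) in Gbp from a 2C flow-cytometry value in pg.

    G_1C = (2C/2) * 0.978, G_1Cx = (2C/ploidy) * 0.978, both reported to
    3 decimals (half-up), the precision genome-size tables print.
    """
    if size_2C_pg <= 0:
        raise ValueError("size_2C_pg must be > 0")
    g1c = _round_half_up(size_2C_pg / 2 * PG_TO_GBP, 3)
    g1cx = _round_half_up(size_2C_pg / ploidy * PG_TO_GBP, 3)
    return g1c, g1cx


def coverage_of_dataset(
    n_reads: int, read_length: int, g1c_gbp: float, dp: int = 2
) -> float:
    """Fold 1C coverage of a dataset, rounded half-up to ``dp`` decimals."""
    if n_reads <= 0 or read_length <= 0 or g1c_gbp <= 0:
        raise ValueError("all inputs must be positive")
    return _round_half_up(n_reads * read_length / (g1c_gbp * 1e9), dp)


def load_sample_table() -> pd.DataFrame:
    """The bundled 11-accession sample sheet (genome sizes, read counts)."""
    with importlib.resources.files("repeatome.data").joinpath(
        "hieracium_samples.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_comparative_table() -> pd.DataFrame:
    """The bundled comparative-run design (equalized read numbers)."""
    with importlib.resources.files("repeatome.data").joinpath(
        "hieracium_comparative.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


# ----------------------------------------------------------------- composition


def composition_table(
    abundance: pd.DataFrame,
    annotations: dict[int, str],
    below_fraction: dict[str, float],
    singlet_fraction: dict[str, float],
    level: str = "supercluster",
) -> pd.DataFrame:
    """Per-sample genomic proportions (%) by repeat category.

    ``abundance`` is the (cluster_id, sample, count, proportion) table of
    above-threshold clusters; ``annotations`` the effective lineage per
    cluster at the requested level.  Category rows plus the small-cluster
    and singlet masses must close to 100 % within 0.01.
    """
    from .annotate import classify_category

    samples = sorted(abundance["sample"].unique())
    cats: dict[str, dict[str, float]] = {}
    for _, row in abundance.iterrows():
        lin = annotations.get(int(row["cluster_id"]), "unclassified")
        cat = classify_category(lin) if lin != "unclassified" else "unclassified"
        cats.setdefault(cat, {s: 0.0 for s in samples})
        cats[cat][row["sample"]] += 100.0 * row["proportion"]
    rows = []
    for cat in sorted(cats):
        rows.append({"category": cat, **cats[cat]})
    above_total = {
        s: sum(c[s] for c in cats.values()) for s in samples
    }
    rows.append({"category": "total above threshold", **above_total})
    rows.append(
        {
            "category": "small uncharacterized clusters",
            **{s: 100.0 * below_fraction.get(s, 0.0) for s in samples},
        }
    )
    rows.append(
        {
            "category": "singlets",
            **{s: 100.0 * singlet_fraction.get(s, 0.0) for s in samples},
        }
    )
    table = pd.DataFrame(rows).set_index("category")
    table.attrs["level"] = level
    for s in samples:
        closure = (
            above_total[s]
            + 100.0 * below_fraction.get(s, 0.0)
            + 100.0 * singlet_fraction.get(s, 0.0)
        )
        if abs(closure - 100.0) > 0.01:
            raise ValueError(
                f"composition closure violated for {s}: {closure:.4f}% "
                f"(unaccounted {100.0 - closure:+.4f}%)"
            )
    return table


# -------------------------------------------------------------------- pipeline


def _require(manifest: dict, key: str, ctx: str = "manifest"):
    if key not in manifest:
        raise ValueError(f"{ctx}: missing required key {key!r}")
    return manifest[key]


def run_pipeline(manifest: dict | str | Path, outdir: str | Path) -> Path:
    """Run a whole analysis from a YAML manifest and write TSV artifacts.

    Modes: ``comparative`` (simulate parents + hybrids, equalize coverage,
    joint-cluster, deviation scores), ``individual`` (one sample,
    clustering + annotation + composition) and ``bias`` (tiered
    subsampling comparisons).  Re-running with the same manifest
    reproduces byte-identical outputs.
    """
    from . import pipeline as _pl

    if not isinstance(manifest, dict):
        manifest = yaml.safe_load(Path(manifest).read_text())
    mode = _require(manifest, "mode")
    seed = int(_require(manifest, "seed"))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if mode == "comparative":
        result = _pl.comparative_mode(manifest, seed)
    elif mode == "individual":
        result = _pl.individual_mode(manifest, seed)
    elif mode == "bias":
        result = _pl.bias_mode(manifest, seed)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for name, obj in result.items():
        path = outdir / f"{name}.tsv"
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t", index=True, float_format="%.6g")
        else:
            (outdir / f"{name}.json").write_text(
                json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n"
            )
    return outdir


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
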