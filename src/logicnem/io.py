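"""Reading and writing the package's file formats.

Effect matrices travel as TSV/CSV: reporter identifiers in the first
column, canonical experiment labels in the header (single knockout = gene
name, double = sorted names joined by ':'; an import shim accepts the
dot-separated dialect common in expression-screen exports), cells 0/1.
Replicate columns share a label with a ``#k`` suffix.  Continuous matrices
are accepted only with an explicit binarization threshold (effect iff
|value| >= threshold).

Networks are serialized as JSON (nodes, edges, gates with ordered parents)
and exported as SIF for network viewers.  Result files are TSV or JSON
lines with a comment header embedding the tool version, seed and a config
hash, so every output is reproducible from its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import DataFormatError, ValidationError
from .graph import (
    Gate,
    PerturbationExperiment,
    SignalingGraph,
    build_design_matrix,
    canonical_label,
)
from .inference import ModelHypothesis
from .likelihood import EffectDataset, NoiseRates
from .screening import ScreenResult
from .simulation import simulate_data

__all__ = [
    "read_effect_matrix",
    "write_effect_matrix",
    "write_results",
    "read_results_jsonl",
    "fixture_generator",
    "normalize_experiment_label",
]

_REPLICATE_RE = re.compile(r"^(?P<base>.+)#(?P<rep>\d+)$")


def normalize_experiment_label(raw: str) -> str:
    """Canonicalize an experiment label.

    Accepts 'A:B' (canonical) and the dot-separated 'A.B' shim; gene order
    is normalized by sorting.  Single labels and 'WT' pass through.
    """
    raw = raw.strip()
    if raw in ("WT", "wt", ""):
        return "WT"
    if ":" in raw:
        genes = raw.split(":")
    elif "." in raw:
        genes = raw.split(".")
    else:
        genes = [raw]
    genes = [g.strip() for g in genes]
    if any(not g for g in genes):
        raise DataFormatError(f"malformed experiment label {raw!r}")
    if len(genes) > 2:
        raise DataFormatError(
            f"label {raw!r} names {len(genes)} genes; only single and double "
            "knockouts are supported"
        )
    return canonical_label(genes)


def read_effect_matrix(
    path,
    sep: str | None = None,
    threshold: float | None = None,
) -> EffectDataset:
    """Read a delimited effect matrix into an ``EffectDataset``.

    ``sep`` defaults to tab for .tsv/.txt and comma for .csv.  With
    ``threshold`` set, continuous cells are binarized as
    |value| >= threshold; without it any non-binary cell is an error naming
    its row and column.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # noqa: BLE001 - wrap parser errors uniformly
        raise DataFormatError(f"could not parse {path}: {exc}") from exc
    if frame.index.has_duplicates:
        dupes = sorted(frame.index[frame.index.duplicated()].unique())
        raise DataFormatError(f"duplicate reporter IDs in {path}: {dupes[:5]}")

    # group replicate columns by base label
    groups: dict[str, list[str]] = {}
    for col in frame.columns:
        mobj = _REPLICATE_RE.match(str(col))
        base = mobj.group("base") if mobj else str(col)
        groups.setdefault(normalize_experiment_label(base), []).append(col)
    counts = {len(cols) for cols in groups.values()}
    if len(counts) > 1:
        raise DataFormatError(
            f"unequal replicate counts per experiment in {path}: "
            + ", ".join(f"{k}={len(v)}" for k, v in sorted(groups.items()))
        )
    l = counts.pop() if counts else 1

    values = np.empty((frame.shape[0], len(groups), l))
    labels = list(groups)
    for j, lbl in enumerate(labels):
        block = frame[groups[lbl]].to_numpy(dtype=float)
        values[:, j, :] = block
    if threshold is not None:
        values = (np.abs(values) >= threshold).astype(np.uint8)
    else:
        bad = ~np.isin(values, (0.0, 1.0))
        if bad.any():
            i, j, k = np.argwhere(bad)[0]
            raise DataFormatError(
                f"non-binary cell {values[i, j, k]!r} at reporter "
                f"{frame.index[i]!r}, experiment {labels[j]!r} in {path}; "
                "pass a binarization threshold to accept continuous values"
            )
    try:
        return EffectDataset(
            [str(r) for r in frame.index], labels, values.astype(np.uint8)
        )
    except ValidationError as exc:
        raise DataFormatError(f"{path}: {exc}") from exc


def write_effect_matrix(data: EffectDataset, path, sep: str = "\t") -> None:
    data.to_frame().to_csv(path, sep=sep, index_label="reporter")


def _config_hash(config: Mapping | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header_lines(seed, config) -> list[str]:
    return [
        f"# logicnem {__version__}",
        f"# seed: {seed}",
        f"# config: {_config_hash(config)}",
    ]


def _record_of(result) -> dict:
    if isinstance(result, ModelHypothesis):
        return {
            "type": "model",
            "graph": result.graph.to_dict(),
            "score": result.score,
            "equivalence_class_id": result.equivalence_class_id,
        }
    if isinstance(result, ScreenResult):
        return {
            "type": "screen",
            "pair": list(result.pair),
            "modulator": result.modulator,
            "category": result.category,
            "labels": list(result.labels),
            "ambiguous": result.ambiguous,
            "score": result.score,
            "margin": result.margin,
            "n_common_reporters": result.n_common_reporters,
        }
    if dataclasses.is_dataclass(result):
        return dataclasses.asdict(result)
    return dict(result)


def write_results(
    results: Sequence,
    path,
    format: str = "tsv",
    seed=None,
    config: Mapping | None = None,
) -> None:
    """Write search or screen results with a reproducibility header.

    ``format`` is ``tsv`` (flat table), ``jsonl`` (one JSON record per
    line, round-trips through ``read_results_jsonl``) or ``sif`` (edge list
    of the top model).  Ordering is the caller's, which searches already
    make deterministic.
    """
    path = Path(path)
    header = _header_lines(seed, config)
    if format == "jsonl":
        with open(path, "w") as fh:
            for line in header:
                fh.write(line + "\n")
            for r in results:
                fh.write(json.dumps(_record_of(r), sort_keys=True) + "\n")
    elif format == "tsv":
        records = [_record_of(r) for r in results]
        for rec in records:
            if "graph" in rec:
                graph = rec.pop("graph")
                rec["edges"] = ";".join(f"{p}->{c}" for p, c in graph["edges"])
                rec["gates"] = ";".join(
                    f"{c}:{g['label']}({g['parent_a']},{g['parent_b']})"
                    for c, g in graph["gates"].items()
                )
            if "pair" in rec:
                rec["pair"] = canonical_label(rec["pair"])
            if "labels" in rec:
                rec["labels"] = ";".join(rec["labels"])
        frame = pd.DataFrame.from_records(records)
        with open(path, "w") as fh:
            for line in header:
                fh.write(line + "\n")
            frame.to_csv(fh, sep="\t", index=False)
    elif format == "sif":
        if not results:
            text = ""
        else:
            first = results[0]
            graph = first.graph if isinstance(first, ModelHypothesis) else first
            text = graph.to_sif()
        with open(path, "w") as fh:
            for line in header:
                fh.write(line + "\n")
            fh.write(text)
    else:
        raise ValidationError(f"unknown result format {format!r}")


def read_results_jsonl(path) -> list[dict]:
    """Read back a JSONL result file, skipping the comment header."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(json.loads(line))
    return out


# -- example bundles ----------------------------------------------------

FIXTURE_KINDS = ("fig2a", "planted-modulator", "benchmark-mini", "gln3-like-triple")

#: the four-node nested pathway used throughout the documentation:
#: A -> C -> D with a second input B -> D combined by OR at D.
NESTED_EXAMPLE = SignalingGraph(
    ("A", "B", "C", "D"),
    [("A", "C"), ("C", "D"), ("B", "D")],
    {"D": Gate("OR", "C", "B")},
)


def fixture_generator(kind: str, seed: int, outdir) -> dict[str, Path]:
    """Write a small on-disk example bundle; byte-identical given the seed.

    * ``fig2a``: the nested OR pathway with its noise-free design matrix.
    * ``planted-modulator``: a pair gating a child by AND among decoys.
    * ``benchmark-mini``: a benchmark config at desk scale.
    * ``gln3-like-triple``: a masking (NOT-B style) modulator planted among
      decoys, emulating the repressor-masks-activator geometry seen in
      nitrogen-metabolism screens in yeast (synthetic stand-in, no real
      expression data).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}
    if kind == "fig2a":
        graph = NESTED_EXAMPLE
        experiments = [PerturbationExperiment([g]) for g in graph.nodes]
        phi = build_design_matrix(graph, experiments)
        theta_assign = np.arange(4)
        from .likelihood import AttachmentMap

        theta = AttachmentMap(graph.nodes, theta_assign, ("EA", "EB", "EC", "ED"))
        data = simulate_data(graph, theta, experiments, NoiseRates(0.0, 0.0), rng=rng)
        paths["network"] = outdir / "network.json"
        graph.to_json(paths["network"])
        paths["data"] = outdir / "data.tsv"
        write_effect_matrix(data, paths["data"])
        paths["expected"] = outdir / "expected.json"
        with open(paths["expected"], "w") as fh:
            json.dump(
                {
                    "design_matrix": phi.states.tolist(),
                    "experiments": list(phi.labels),
                    "genes": list(phi.genes),
                },
                fh,
                indent=2,
            )
    elif kind in ("planted-modulator", "gln3-like-triple"):
        if kind == "planted-modulator":
            genes = ("X", "Y", "Z", "W")
            gate = Gate("AND", "X", "Y")
            planted_gate = "AND"
        else:
            # activator/repressor pair; the modulator's effect on the
            # activator's targets is masked by the repressor (NOT-B with
            # the pair ordered (activator, repressor))
            genes = ("act1", "rep1", "mod1", "dec1")
            gate = Gate("NOT-B", "act1", "rep1")
            planted_gate = "NOT-B"
        x, y, z, w = genes
        graph = SignalingGraph(genes, [(x, z), (y, z)], {z: gate})
        experiments = [PerturbationExperiment([g]) for g in genes]
        experiments.append(PerturbationExperiment([x, y]))
        from .likelihood import AttachmentMap

        m = 60
        assignment = rng.integers(0, 4, size=m)
        theta = AttachmentMap(genes, assignment, tuple(f"E{i+1}" for i in range(m)))
        data = simulate_data(graph, theta, experiments, NoiseRates(0.1, 0.1), rng=rng)
        paths["network"] = outdir / "network.json"
        graph.to_json(paths["network"])
        paths["data"] = outdir / "data.tsv"
        write_effect_matrix(data, paths["data"])
        paths["expected"] = outdir / "expected.json"
        with open(paths["expected"], "w") as fh:
            json.dump(
                {"pair": [x, y], "modulator": z, "gate": planted_gate, "decoy": w},
                fh,
                indent=2,
            )
    elif kind == "benchmark-mini":
        config = {
            "seed": seed,
            "n_genes": 4,
            "n_reporters": 40,
            "alpha": 0.1,
            "beta_grid": [0.01, 0.1],
            "n_networks": 5,
            "replicates": 1,
        }
        paths["config"] = outdir / "config.yaml"
        import yaml

        with open(paths["config"], "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=True)
    else:
        raise ValidationError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    return paths
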