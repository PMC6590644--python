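"""Reading meta-analytic tables and serializing fitted trees.

Input is a delimited text file (CSV/TSV) with a header, plus a schema —
a mapping (or YAML/JSON sidecar file) declaring column roles::

    effect: d            # column with the observed effect sizes
    variance: v          # or  se: se_d  (squared on read)
    moderators:
      T1: binary
      dose: continuous
      quality: ordinal
    ordinal_levels:
      quality: [low, medium, high]

Fitted results round-trip through a JSON document holding the node
structure, split rules, per-node summaries, the pruning trace and the
final subgroup meta-analysis.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import EffectSizeSet
from .prune import MetaCartResult

__all__ = ["read_schema", "read_dataset", "write_tree", "read_tree"]


def read_schema(schema) -> dict:
    """Accept a dict, or a path to a YAML/JSON schema sidecar."""
    if isinstance(schema, dict):
        return schema
    text = Path(schema).read_text()
    return yaml.safe_load(text)


def read_dataset(path, schema) -> EffectSizeSet:
    """Load a delimited study table into an :class:`EffectSizeSet`.

    The delimiter is sniffed from the extension (.tsv -> tab, else comma).
    Rows with missing effect sizes or variances are rejected with their
    indices; a declared standard-error column is squared to a variance.
    """
    schema = read_schema(schema)
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)

    eff_col = schema["effect"]
    if "variance" in schema:
        var = pd.to_numeric(df[schema["variance"]], errors="coerce")
    elif "se" in schema:
        var = pd.to_numeric(df[schema["se"]], errors="coerce") ** 2
    else:
        raise ValueError("schema must declare a 'variance' or 'se' column")
    d = pd.to_numeric(df[eff_col], errors="coerce")

    bad = df.index[d.isna() | var.isna()].tolist()
    if bad:
        raise ValueError(f"missing/non-numeric effect or variance in rows {bad}")
    neg = df.index[var <= 0].tolist()
    if neg:
        raise ValueError(f"nonpositive sampling variance in rows {neg}")

    mods = schema.get("moderators", {})
    missing = [c for c in mods if c not in df.columns]
    if missing:
        raise ValueError(f"moderator columns not in file: {missing}")
    return EffectSizeSet(
        d=d.to_numpy(), var=var.to_numpy(),
        X=df[list(mods)].copy(), types=dict(mods),
        ordinal_levels=dict(schema.get("ordinal_levels", {})),
        ids=df.index.tolist(),
    )


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (tuple, set, frozenset)):
        return [_jsonable(v) for v in x]
    return x


def write_tree(result: MetaCartResult, path) -> dict:
    """Serialize a fitted tree to a JSON document; returns the document.

    The document records every grown node (id, parent, rule, members,
    summary, Q), the split order, the kept (post-pruning) internal set,
    the CV curve, tau^2, Q_B, df, p-value, per-subgroup CIs, and the
    software version and seed, so results are fully reproducible.
    """
    tree, fit = result.tree, result.fit
    doc = {
        "software": {"name": "metatree", "version": __version__},
        "model": result.model,
        "c": result.c,
        "seed": result.seed,
        "alpha": result.alpha,
        "min_node_size": tree.min_size,
        "n_terminal": result.size,
        "nodes": [
            {
                "id": n.id, "parent": n.parent,
                "members": n.members.tolist(),
                "d_plus": n.d_plus, "q": n.q, "depth": n.depth,
                "left": n.left, "right": n.right,
                "rule": None if n.rule is None else {
                    "mod": n.rule.mod, "col": n.rule.col,
                    "kind": n.rule.kind,
                    "threshold": None if np.isnan(n.rule.threshold)
                    else n.rule.threshold,
                    "left_codes": list(n.rule.left_codes),
                    "observed_codes": list(n.rule.observed_codes),
                    "left_values": [_jsonable(v) for v in n.rule.left_values],
                },
            }
            for n in tree.nodes
        ],
        "split_order": list(tree.split_order),
        "kept": sorted(result.kept),
        "re_path": tree.re_path,
        "cv": {
            "sizes": result.curve.sizes.tolist(),
            "errors": result.curve.errors.tolist(),
            "ses": result.curve.ses.tolist(),
            "seed": result.curve.seed,
        },
        "fit": {
            "J": fit.J, "df": fit.df, "tau2": fit.tau2,
            "q_between": fit.q_between, "q_total": fit.q_total,
            "pvalue": fit.pvalue, "grand_mean": fit.grand_mean,
            "sizes": fit.sizes.tolist(), "means": fit.means.tolist(),
            "q_within": fit.q_within.tolist(),
            "ci95": result.ci(0.95).tolist(),
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))
    return doc


def read_tree(path) -> dict:
    """Load a serialized tree document (as a plain dict)."""
    return json.loads(Path(path).read_text())
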