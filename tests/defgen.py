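"""Random toy points-score definitions for oracle-equivalence tests."""

from __future__ import annotations

import numpy as np


def random_points_doc(rng: np.random.Generator) -> dict:
    """A random, schema-valid points definition over 2-4 variables."""
    n_vars = int(rng.integers(2, 5))
    variables = []
    rules = []
    continuous_names = []
    for i in range(n_vars):
        name = f"v{i}"
        if rng.random() < 0.6:
            variables.append({"name": name, "kind": "continuous"})
            cuts = sorted(set(float(c) for c in
                              rng.uniform(-50, 50, int(rng.integers(1, 5)))))
            edges = [None, *cuts, None]
            bands = [{"lo": lo, "hi": hi,
                      "points": int(rng.integers(0, 10))}
                     for lo, hi in zip(edges, edges[1:])]
            rules.append({"variable": name, "type": "range", "bands": bands})
            continuous_names.append(name)
        else:
            variables.append({"name": name, "kind": "categorical"})
            cats = [f"c{j}" for j in range(int(rng.integers(2, 5)))]
            rules.append({"variable": name, "type": "category",
                          "points": {c: int(rng.integers(0, 10))
                                     for c in cats}})
    # optionally restate the first rule as stratified by a continuous var
    if len(continuous_names) >= 2 and rng.random() < 0.5:
        target, stratifier = continuous_names[0], continuous_names[1]
        cut = float(rng.uniform(-30, 30))
        strata = []
        for lo, hi in ((None, cut), (cut, None)):
            cuts = sorted(set(float(c) for c in
                              rng.uniform(-50, 50, int(rng.integers(1, 4)))))
            edges = [None, *cuts, None]
            strata.append({"stratum": {"lo": lo, "hi": hi},
                           "bands": [{"lo": a, "hi": b,
                                      "points": int(rng.integers(0, 10))}
                                     for a, b in zip(edges, edges[1:])]})
        rules = [r for r in rules if r["variable"] != target]
        rules.append({"variable": target, "type": "range",
                      "stratify_by": stratifier, "strata": strata})
    return {"id": "toy", "method": "points_table", "horizons": [1],
            "completeness": "require_complete", "variables": variables,
            "rules": rules, "clamp_points": True, "risk": {1: {0: 0.1}}}


def random_row(doc: dict, rng: np.random.Generator) -> dict:
    row = {}
    for rule in doc["rules"]:
        name = rule["variable"]
        if rule["type"] == "category":
            cats = list(rule["points"])
            row[name] = cats[int(rng.integers(0, len(cats)))]
        else:
            row[name] = float(rng.uniform(-80, 80))
    for v in doc["variables"]:  # stratifiers without own rule, if any
        row.setdefault(v["name"], float(rng.uniform(-80, 80)))
    return row
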