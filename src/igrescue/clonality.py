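"""Three-layer repertoire clonality summary and cross-sample tracking.

A repertoire's clonal structure is summarized per chain view as three
nested layers, the way repertoire donut charts are conventionally
drawn:

* **inner** — frequency mass of clonotypes seen once, twice, and three
  or more times ("3+");
* **quantile** — clonotypes ranked by abundance and partitioned into
  five equal-size rank bins (top 20% of clonotypes = Q1, next 20% =
  Q2, ...), each bin's total frequency;
* **top** — the individual frequencies of the five most abundant
  clonotypes.

Frequencies are over productive clonotypes; ranking ties break by
junction sequence so the profile is a pure function of the table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .junctions import ClonotypeTable


class CloneProfileError(ValueError):
    pass


@dataclass
class RepertoireProfile:
    sample_id: str
    chain_view: str
    inner_layer: dict[str, float]  # masses of the "1", "2", "3+" bins
    quantile_layer: dict[str, float]  # Q1..Q5
    top_layer: list[tuple[str, float]]  # (junction_nt, frequency), top 5

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "chain_view": self.chain_view,
            "inner_layer": self.inner_layer,
            "quantile_layer": self.quantile_layer,
            "top_layer": [
                {"junction": j, "frequency": f} for j, f in self.top_layer
            ],
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def profile_repertoire(
    table: ClonotypeTable, sample_id: str, chain_view: str = "H"
) -> RepertoireProfile:
    """Compute the three-layer clonality profile for one chain view.

    Only productive clonotypes (the ones carrying frequency) enter the
    profile.  When the clonotype count is not divisible by five, the
    remainder clonotypes go to the earlier quantile bins, so bin sizes
    are non-increasing and Q1 >= Q2 >= ... >= Q5 holds.
    """
    view = table.view(chain_view)
    rows = [c for c in view.clonotypes if c.productive]
    if not rows:
        raise CloneProfileError(f"no productive clonotypes in view {chain_view!r}")
    rows.sort(key=lambda c: (-c.frequency, c.junction_nt, c.v_call, c.j_call))

    inner = {"1": 0.0, "2": 0.0, "3+": 0.0}
    for c in rows:
        inner["1" if c.count == 1 else "2" if c.count == 2 else "3+"] += c.frequency

    n = len(rows)
    base, rem = divmod(n, 5)
    quantiles: dict[str, float] = {}
    at = 0
    for q in range(5):
        size = base + (1 if q < rem else 0)
        quantiles[f"Q{q + 1}"] = sum(c.frequency for c in rows[at : at + size])
        at += size

    top = [(c.junction_nt, c.frequency) for c in rows[:5]]
    return RepertoireProfile(sample_id, chain_view, inner, quantiles, top)


def cross_sample_tracking(
    tables: dict[str, ClonotypeTable], chain_view: str = "H"
) -> pd.DataFrame:
    """Per-sample frequency matrix of every clonotype seen in any sample.

    Rows are clonotype keys (locus, v_call, j_call, junction); one
    column per sample plus a ``rank1_in`` column listing the samples
    where that clonotype is the most abundant one.
    """
    if len(tables) < 2:
        raise CloneProfileError("cross-sample tracking needs at least two samples")
    freq: dict[tuple, dict[str, float]] = {}
    rank1: dict[str, tuple] = {}
    for sample, table in tables.items():
        view = table.view(chain_view)
        rows = sorted(
            (c for c in view.clonotypes if c.productive),
            key=lambda c: (-c.frequency, c.junction_nt),
        )
        for c in rows:
            freq.setdefault(c.key, {})[sample] = c.frequency
        if rows:
            rank1[sample] = rows[0].key
    samples = sorted(tables)
    records = []
    for key, per_sample in sorted(freq.items()):
        rec = {
            "locus": key[0], "v_call": key[1], "j_call": key[2], "junction": key[3],
        }
        for s in samples:
            rec[s] = per_sample.get(s, 0.0)
        rec["rank1_in"] = ",".join(s for s in samples if rank1.get(s) == key)
        records.append(rec)
    return pd.DataFrame.from_records(records)


def donut_svg(profile: RepertoireProfile, path: str | Path) -> None:
    """Render the three-layer profile as a donut chart (thin reporting layer)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    layers = [
        list(profile.inner_layer.items()),
        list(profile.quantile_layer.items()),
        [(j[:8], f) for j, f in profile.top_layer]
        + ([("rest", 1 - sum(f for _, f in profile.top_layer))]
           if sum(f for _, f in profile.top_layer) < 1 else []),
    ]
    for depth, layer in enumerate(layers):
        vals = [v for _, v in layer]
        labels = [k for k, _ in layer]
        ax.pie(
            vals,
            radius=0.5 + 0.25 * depth,
            labels=labels if depth == 2 else None,
            wedgeprops=dict(width=0.23, edgecolor="w"),
            startangle=90,
            textprops={"fontsize": 6},
        )
    ax.set(aspect="equal", title=f"{profile.sample_id} {profile.chain_view}")
    fig.savefig(path, format="svg")
    plt.close(fig)
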