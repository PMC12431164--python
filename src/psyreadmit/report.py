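"""Descriptive summaries and text rendering of result matrices.

Mirrors the study's reporting conventions: a per-site descriptive table
(counts with one-decimal percentages, mean (SD) and median (IQR) for the
numeric covariates, outcome mean), odds-ratio tables for the logistic fits,
permutation-importance tables for the forests, and a text grid of the
cross-site matrices in which only metric values above a display threshold
(default 0.6) are shown.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DIAG_FLAGS, RACE_LEVELS
from .transport import CrossSiteMatrix


def _pct(k: int, n: int) -> str:
    return f"{k} ({100.0 * k / n:.1f})" if n else "0 (0.0)"


def describe_site(instances: pd.DataFrame) -> pd.DataFrame:
    """Table-style descriptive summary of one site's instances."""
    n = len(instances)
    rows: list[tuple[str, str]] = [("n", str(n))]
    los = instances["los"].astype(float)
    rows.append(("LOS, mean (SD)", f"{los.mean():.3g} ({los.std(ddof=1):.3g})"))
    q1, med, q3 = np.percentile(los, [25, 50, 75])
    rows.append(("LOS, median (IQR)", f"{med:.3g} ({q1:.3g}-{q3:.3g})"))
    for level in ("female", "male", "missing"):
        rows.append((f"Sex {level}, n (%)", _pct(int((instances['sex'] == level).sum()), n)))
    for level in RACE_LEVELS:
        rows.append((f"Race {level}, n (%)", _pct(int((instances['race'] == level).sum()), n)))
    age = instances["age"].astype(float)
    rows.append(("Age, mean (SD)", f"{age.mean():.3g} ({age.std(ddof=1):.3g})"))
    for flag in DIAG_FLAGS:
        rows.append((f"{flag.capitalize()}, n (%)", _pct(int(instances[flag].sum()), n)))
    y = instances["readmitted"].astype(float)
    rows.append(("Readmitted 30d, mean (SD)", f"{y.mean():.3f} ({y.std(ddof=1):.3f})"))
    return pd.DataFrame(rows, columns=["statistic", "value"])


def describe_sites(instances: pd.DataFrame) -> pd.DataFrame:
    """Wide descriptive table, one column per site."""
    pieces = {}
    for site, grp in instances.groupby("site", sort=True):
        tab = describe_site(grp).set_index("statistic")["value"]
        pieces[site] = tab
    return pd.DataFrame(pieces)


def render_matrix(
    matrix: CrossSiteMatrix,
    display_threshold: float = 0.6,
    annotate: dict[str, pd.DataFrame] | pd.DataFrame | None = None,
) -> str:
    """Text grid of mean AUC and F1; values at or below the display threshold
    are blanked (set the threshold to 0 to show everything).  Diagonal
    (in-site) cells are marked with '*'.  ``annotate`` optionally adds a
    signed per-cell delta (e.g. adjusted minus unadjusted), either one frame
    for both metrics or a dict keyed by metric."""
    lines = [
        f"{matrix.model_kind} model | n_sub={matrix.n_sub}, n_reps={matrix.n_reps} "
        f"(values <= {display_threshold:g} blanked)"
    ]
    width = 12 if annotate is None else 16
    for metric in ("auc", "f1"):
        frame = matrix.metric_frame(metric)
        ann = annotate.get(metric) if isinstance(annotate, dict) else annotate
        lines.append(f"\n{metric.upper()} (rows = training site, cols = testing site)")
        lines.append(f"{'':>8}" + "".join(f"{t:>{width}}" for t in matrix.sites))
        for s in matrix.sites:
            cells = []
            for t in matrix.sites:
                v = frame.loc[s, t]
                mark = "*" if s == t else " "
                text = f"{v:.3f}{mark}" if v > display_threshold else f"     {mark}"
                if ann is not None:
                    d = ann.loc[s, t]
                    text += f" ({d:+.2f})" if not np.isnan(d) else "        "
                cells.append(f"{text:>{width}}")
            lines.append(f"{s:>8}" + "".join(cells))
    return "\n".join(lines)


def export_matrices(
    matrices: list[CrossSiteMatrix],
    display_threshold: float = 0.6,
) -> tuple[pd.DataFrame, str]:
    """(long-format CSV table with unmasked values, masked text report)."""
    long = pd.concat([m.to_long() for m in matrices], ignore_index=True)
    text = "\n\n".join(render_matrix(m, display_threshold) for m in matrices)
    return long, text
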