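"""Block averaging and the split-plot-in-time comparison of conditions.

The experiment crosses two factors — rearing temperature (23 °C comfort vs.
31 °C heat stress, the whole-plot factor) and environmental enrichment
(enriched vs. nonenriched pen, the subplot factor) — observed over a 7-hour
session divided into 14 half-hour time blocks (the repeated measures, 1800
frames each at 1 fps). Per-frame index series are averaged within blocks, and
block means feed a split-plot ANOVA:

    y ~ temperature * enrichment + block + temperature:block

with the temperature main effect tested against the temperature × block mean
square (whole-plot error) and enrichment and the interaction tested against
the residual (subplot error). Post-hoc separation of the four condition means
uses Tukey's HSD with a compact letter display.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, ParameterError
from .indices import IndexSeries

Response = Literal["cluster", "unrest"]

TEMPERATURE_LEVELS = ("comfort", "heat_stress")
ENRICHMENT_LEVELS = ("enriched", "nonenriched")


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of the 2 × 2 split-plot experiment in time.

    Defaults mirror a 7-h session at 1 fps split into 14 thirty-minute
    blocks; scaled-down designs (shorter blocks) are valid as long as the
    session divides evenly into blocks.
    """

    temperature_levels: tuple[str, ...] = TEMPERATURE_LEVELS
    enrichment_levels: tuple[str, ...] = ENRICHMENT_LEVELS
    block_duration_min: float = 30.0
    session_hours: float = 7.0
    sample_rate_fps: float = 1.0

    def __post_init__(self) -> None:
        if not self.temperature_levels or not self.enrichment_levels:
            raise DesignError("factor levels must be non-empty")
        if self.block_duration_min <= 0 or self.session_hours <= 0:
            raise DesignError("durations must be positive")
        n = self.session_hours * 60.0 / self.block_duration_min
        if abs(n - round(n)) > 1e-9:
            raise DesignError(
                f"session of {self.session_hours} h does not divide into "
                f"{self.block_duration_min}-min blocks"
            )

    @property
    def n_blocks(self) -> int:
        return round(self.session_hours * 60.0 / self.block_duration_min)

    @property
    def frames_per_block(self) -> int:
        return round(self.block_duration_min * 60.0 * self.sample_rate_fps)

    @property
    def frames_per_condition(self) -> int:
        return self.n_blocks * self.frames_per_block

    @property
    def n_conditions(self) -> int:
        return len(self.temperature_levels) * len(self.enrichment_levels)

    @property
    def total_frames(self) -> int:
        return self.frames_per_condition * self.n_conditions


@dataclass
class BlockSummary:
    """Mean indices of one time block under one condition."""

    block_id: int
    temperature: str
    enrichment: str
    mean_cluster: float | None
    mean_unrest: float | None
    n_valid_frames: int

    @property
    def condition(self) -> str:
        return f"{self.temperature}:{self.enrichment}"


def block_averages(
    series: IndexSeries,
    design: ExperimentDesign,
    condition_labels: tuple[str, str],
) -> list[BlockSummary]:
    """Average an index series into the design's time blocks.

    Invalid frames are excluded from the means and counted out of
    ``n_valid_frames``; a block with zero valid frames gets missing means.
    Unrest entries are keyed by the later frame of each pair and assigned to
    that frame's block.
    """
    temperature, enrichment = condition_labels
    per_block = design.frames_per_block
    summaries = []
    df = series.to_dataframe()
    df["block_id"] = df["frame_index"] // per_block + 1
    for block_id in range(1, design.n_blocks + 1):
        sub = df[df["block_id"] == block_id]
        valid_cluster = sub.loc[sub["valid"], "cluster_index"].dropna()
        valid_unrest = sub["unrest_cm"].dropna()
        summaries.append(
            BlockSummary(
                block_id=block_id,
                temperature=temperature,
                enrichment=enrichment,
                mean_cluster=float(valid_cluster.mean()) if len(valid_cluster) else None,
                mean_unrest=float(valid_unrest.mean()) if len(valid_unrest) else None,
                n_valid_frames=int(sub["valid"].sum()),
            )
        )
    return summaries


def blocks_to_dataframe(blocks: Sequence[BlockSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "block_id": b.block_id,
                "temperature": b.temperature,
                "enrichment": b.enrichment,
                "mean_cluster": b.mean_cluster,
                "mean_unrest": b.mean_unrest,
                "n_valid_frames": b.n_valid_frames,
            }
            for b in blocks
        ]
    )


def _response_frame(blocks: Sequence[BlockSummary], response: Response) -> pd.DataFrame:
    col = "mean_cluster" if response == "cluster" else "mean_unrest"
    df = blocks_to_dataframe(blocks).rename(columns={col: "y"})
    n_missing = df["y"].isna().sum()
    if n_missing:
        warnings.warn(
            f"{n_missing} block(s) with missing {response} means dropped "
            "listwise from the analysis",
            stacklevel=3,
        )
        df = df.dropna(subset=["y"])
    return df[["block_id", "temperature", "enrichment", "y"]]


def _safe_f(ms_effect: float, ms_error: float, df_num: int, df_den: int) -> tuple[float, float]:
    """F ratio with the degenerate zero-variance cases pinned down.

    Both mean squares zero (identical data) → no evidence of an effect:
    F = 0, p = 1. Zero error with a real effect → F = ∞, p = 0.
    """
    if ms_error <= 0:
        if ms_effect <= 0:
            return 0.0, 1.0
        return math.inf, 0.0
    f = ms_effect / ms_error
    return f, float(sps.f.sf(f, df_num, df_den))


@dataclass
class SplitPlotAnovaResult:
    """ANOVA table plus the model description, statsmodels-results style."""

    table: pd.DataFrame
    response: Response
    model_formula: str
    n_blocks_used: int
    balanced: bool

    def summary(self) -> str:
        lines = [
            f"Split-plot ANOVA (response: {self.response})",
            f"model: {self.model_formula}",
            f"blocks used: {self.n_blocks_used}"
            + ("" if self.balanced else "  [unbalanced: approximate F-tests]"),
            "",
            self.table.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def split_plot_anova(
    blocks: Sequence[BlockSummary],
    response: Response = "unrest",
) -> SplitPlotAnovaResult:
    """Split-plot repeated-measures ANOVA of block means.

    Temperature (whole plot) is tested against the temperature × block
    interaction; enrichment and temperature × enrichment (subplot) against
    the residual. Requires at least two blocks per condition; an unbalanced
    layout is analysed with a warning using the same error strata.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = _response_frame(blocks, response)
    temps = df["temperature"].unique()
    enrichs = df["enrichment"].unique()
    if len(temps) < 2 or len(enrichs) < 2:
        raise DesignError(
            "split-plot ANOVA needs >= 2 levels of both temperature and "
            f"enrichment; got {len(temps)} temperature and {len(enrichs)} "
            "enrichment level(s)"
        )
    counts = df.groupby(["temperature", "enrichment"])["y"].count()
    if counts.min() < 2:
        raise DesignError("need >= 2 blocks per condition")
    balanced = counts.nunique() == 1
    if not balanced:
        warnings.warn("unbalanced design: F-tests are approximate", stacklevel=2)

    formula = (
        "y ~ C(temperature) * C(enrichment) + C(block_id) "
        "+ C(temperature):C(block_id)"
    )

    y = df["y"].to_numpy(dtype=float)
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total <= 1e-12 * max(1.0, y.mean() ** 2) * len(y):
        # a constant response carries no evidence of any effect; OLS sums of
        # squares would be pure rounding noise here
        table = pd.DataFrame(
            {
                "factor": ["temperature", "enrichment", "temperature:enrichment"],
                "df_num": [1, 1, 1],
                "df_den": [1, 1, 1],
                "F": [0.0, 0.0, 0.0],
                "p_value": [1.0, 1.0, 1.0],
            }
        ).set_index("factor")
        return SplitPlotAnovaResult(
            table=table,
            response=response,
            model_formula=formula + "  [degenerate: constant response]",
            n_blocks_used=int(df["block_id"].nunique()),
            balanced=balanced,
        )
    with warnings.catch_warnings():
        # zero-variance responses produce harmless divide warnings inside OLS
        warnings.simplefilter("ignore", RuntimeWarning)
        model = smf.ols(formula, data=df).fit()
        aov = sm.stats.anova_lm(model, typ=2)

    def _row(name: str) -> tuple[float, int]:
        return float(aov.loc[name, "sum_sq"]), int(aov.loc[name, "df"])

    ss_t, df_t = _row("C(temperature)")
    ss_e, df_e = _row("C(enrichment)")
    ss_te, df_te = _row("C(temperature):C(enrichment)")
    ss_wp, df_wp = _row("C(temperature):C(block_id)")
    ss_res, df_res = _row("Residual")

    ms = lambda ss, d: ss / d if d > 0 else 0.0
    rows = []
    f_t, p_t = _safe_f(ms(ss_t, df_t), ms(ss_wp, df_wp), df_t, df_wp)
    rows.append(("temperature", df_t, df_wp, f_t, p_t))
    f_e, p_e = _safe_f(ms(ss_e, df_e), ms(ss_res, df_res), df_e, df_res)
    rows.append(("enrichment", df_e, df_res, f_e, p_e))
    f_i, p_i = _safe_f(ms(ss_te, df_te), ms(ss_res, df_res), df_te, df_res)
    rows.append(("temperature:enrichment", df_te, df_res, f_i, p_i))

    table = pd.DataFrame(
        rows, columns=["factor", "df_num", "df_den", "F", "p_value"]
    ).set_index("factor")
    return SplitPlotAnovaResult(
        table=table,
        response=response,
        model_formula=formula + "  [temperature tested vs temperature:block MS]",
        n_blocks_used=int(df["block_id"].nunique()),
        balanced=balanced,
    )


def _compact_letter_display(
    conditions: Sequence[str],
    means: dict[str, float],
    not_different: set[frozenset[str]],
) -> dict[str, str]:
    """Letters such that two conditions share one iff not significantly different.

    Each maximal clique of the "not significantly different" graph gets one
    letter; singletons are their own cliques. Letters are assigned to cliques
    in descending order of their best mean, the usual presentation.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(conditions)
    for pair in not_different:
        a, b = tuple(pair)
        g.add_edge(a, b)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: -max(means[m] for m in c))
    letters: dict[str, list[str]] = {c: [] for c in conditions}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, clique in zip(alphabet, cliques):
        for member in clique:
            letters[member].append(letter)
    return {c: "".join(sorted(v)) for c, v in letters.items()}


def tukey_groups(
    blocks: Sequence[BlockSummary],
    response: Response = "unrest",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey HSD separation of the four condition means.

    Returns one row per temperature × enrichment condition with its mean
    (the plain average of that condition's block means) and a compact letter
    display: conditions sharing a letter are not significantly different at
    ``alpha``.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if not (0 < alpha < 1):
        raise ParameterError("alpha must be in (0, 1)")
    df = _response_frame(blocks, response)
    df["condition"] = df["temperature"] + ":" + df["enrichment"]
    conditions = sorted(df["condition"].unique())
    means = df.groupby("condition")["y"].mean().to_dict()

    if df.groupby("condition")["y"].var(ddof=1).fillna(0).sum() == 0:
        # identical responses within and across groups: nothing separable
        not_different = {
            frozenset((a, b))
            for i, a in enumerate(conditions)
            for b in conditions[i + 1:]
        }
    else:
        res = pairwise_tukeyhsd(df["y"].to_numpy(), df["condition"].to_numpy(), alpha=alpha)
        pairs = list(itertools.combinations(res.groupsunique, 2))
        not_different = {
            frozenset(p) for p, rej in zip(pairs, res.reject) if not rej
        }
    letters = _compact_letter_display(conditions, means, not_different)
    out = pd.DataFrame(
        {
            "condition": conditions,
            "temperature": [c.split(":")[0] for c in conditions],
            "enrichment": [c.split(":")[1] for c in conditions],
            "mean": [means[c] for c in conditions],
            "letters": [letters[c] for c in conditions],
        }
    ).sort_values("mean", ascending=False, ignore_index=True)
    return out


def condition_report(
    blocks: Sequence[BlockSummary],
    alpha: float = 0.05,
) -> str:
    """Markdown table of both indices by temperature × enrichment.

    Mirrors the usual presentation: one row per index × temperature, one
    column per enrichment level, Tukey letters in parentheses.
    """
    lines = [
        "| Index | Temperature | " + " | ".join(ENRICHMENT_LEVELS) + " |",
        "|---|---|" + "---|" * len(ENRICHMENT_LEVELS),
    ]
    for response, name in (("cluster", "Cluster"), ("unrest", "Unrest")):
        tk = tukey_groups(blocks, response=response, alpha=alpha)
        tk = tk.set_index("condition")
        for temp in TEMPERATURE_LEVELS:
            cells = []
            for enr in ENRICHMENT_LEVELS:
                key = f"{temp}:{enr}"
                if key in tk.index:
                    row = tk.loc[key]
                    cells.append(f"{row['mean']:.2f} ({row['letters']})")
                else:
                    cells.append("—")
            lines.append(f"| {name} | {temp} | " + " | ".join(cells) + " |")
    return "\n".join(lines)
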