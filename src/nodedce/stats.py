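"""Cluster and contrast-agent comparisons of the semiquantitative parameters.

The design is a split-plot: cluster (inner/outer) is a within-node factor —
both values come from the same lymph node — while contrast agent (Gd-DTPA
vs Gd-BOPTA) varies between nodes. Main effects and their interaction come
from a mixed two-way ANOVA with node as the blocking unit. Within each
agent, the inner-vs-outer contrast is a paired comparison tested against the
pooled within-node error (the cluster x node-within-agent mean square) and
Bonferroni-adjusted by a factor of 2 for the two agents.

Significance is annotated two-sided at the 0.05 and 0.01 levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from nodedce.image_io import AGENTS, validate_param_table

#: the four parameters the node table carries
PARAMETERS = ("auc", "wash_in", "wash_out", "volume_pct")


@dataclass
class ContrastResult:
    """Within-agent inner-vs-outer paired contrast for one parameter."""

    agent: str
    mean_diff: float  # inner - outer
    t: float
    df: int
    p_unc: float
    p_bonf: float  # min(1, 2 * p_unc): two agents per parameter

    @property
    def direction(self) -> int:
        """Sign of the inner - outer mean difference."""
        return int(np.sign(self.mean_diff))


@dataclass
class AnovaResult:
    """Mixed two-way ANOVA plus within-agent contrasts for one parameter."""

    parameter: str
    p_cluster: float
    p_agent: float | None
    p_interaction: float | None
    f_cluster: float
    f_agent: float | None
    contrasts: dict[str, ContrastResult] = field(default_factory=dict)

    def significance(self, p: float) -> str:
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return "ns"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parameter": self.parameter,
                "effect": "cluster",
                "F": self.f_cluster,
                "p": self.p_cluster,
                "signif": self.significance(self.p_cluster),
            }
        ]
        if self.p_agent is not None:
            rows.append(
                {
                    "parameter": self.parameter,
                    "effect": "agent",
                    "F": self.f_agent,
                    "p": self.p_agent,
                    "signif": self.significance(self.p_agent),
                }
            )
        if self.p_interaction is not None:
            rows.append(
                {
                    "parameter": self.parameter,
                    "effect": "cluster x agent",
                    "F": np.nan,
                    "p": self.p_interaction,
                    "signif": self.significance(self.p_interaction),
                }
            )
        for agent, c in self.contrasts.items():
            rows.append(
                {
                    "parameter": self.parameter,
                    "effect": f"inner vs outer ({agent})",
                    "F": c.t**2,
                    "p": c.p_bonf,
                    "signif": self.significance(c.p_bonf),
                }
            )
        return pd.DataFrame(rows)


def _paired_differences(table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    wide = table.pivot_table(index=["node", "agent"], columns="cluster", values=parameter).reset_index()
    wide["diff"] = wide["inner"] - wide["outer"]
    return wide


def within_agent_contrasts(table: pd.DataFrame, parameter: str) -> dict[str, ContrastResult]:
    """Inner-vs-outer paired contrasts per agent with a pooled error term.

    The error variance is the within-node difference variance pooled across
    both agents (df = N_nodes - n_agents); each agent's contrast is a t test
    of its mean difference against that pooled error, Bonferroni-adjusted by
    the number of agents.
    """
    wide = _paired_differences(table, parameter)
    agents = [a for a in AGENTS if a in set(wide["agent"])]
    n_agents = len(agents)
    ss, df = 0.0, 0
    for a in agents:
        d = wide.loc[wide["agent"] == a, "diff"].to_numpy()
        ss += float(((d - d.mean()) ** 2).sum())
        df += d.size - 1
    out: dict[str, ContrastResult] = {}
    for a in agents:
        d = wide.loc[wide["agent"] == a, "diff"].to_numpy()
        mean_d = float(d.mean())
        if df <= 0 or ss == 0.0:
            # degenerate: no within-node variability at all
            t = 0.0 if mean_d == 0 else np.inf * np.sign(mean_d)
            p = 1.0 if mean_d == 0 else 0.0
        else:
            s2 = ss / df
            t = mean_d / np.sqrt(s2 / d.size)
            p = float(2.0 * sps.t.sf(abs(t), df))
        out[a] = ContrastResult(
            agent=a,
            mean_diff=mean_d,
            t=float(t),
            df=df,
            p_unc=p,
            p_bonf=min(1.0, n_agents * p),
        )
    return out


def two_way_anova(table: pd.DataFrame, parameter: str) -> AnovaResult:
    """Mixed two-way ANOVA (cluster within node, agent between nodes).

    With a single-agent table the agent comparisons are omitted and only the
    within-agent cluster contrast is computed.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}; expected one of {PARAMETERS}")
    table = validate_param_table(table)
    n_agents = table["agent"].nunique()
    contrasts = within_agent_contrasts(table, parameter)

    if n_agents < 2:
        # paired contrast doubles as the cluster effect
        c = next(iter(contrasts.values()))
        return AnovaResult(
            parameter=parameter,
            p_cluster=c.p_unc,
            p_agent=None,
            p_interaction=None,
            f_cluster=c.t**2,
            f_agent=None,
            contrasts=contrasts,
        )

    wide = _paired_differences(table, parameter)
    if np.allclose(wide["diff"], 0.0):
        # no within-node variability at all: the cluster effect is exactly null;
        # the agent effect reduces to a one-way ANOVA on the node means
        groups = [
            ((wide.loc[wide["agent"] == a, "inner"] + wide.loc[wide["agent"] == a, "outer"]) / 2)
            for a in sorted(wide["agent"].unique())
        ]
        if max(g.var(ddof=1) for g in groups) == 0 and all(
            np.isclose(g.mean(), groups[0].mean()) for g in groups
        ):
            f_a, p_a = 0.0, 1.0
        else:
            f_a, p_a = sps.f_oneway(*groups)
        return AnovaResult(parameter, 1.0, float(p_a), 1.0, 0.0, float(f_a), contrasts=contrasts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=table, dv=parameter, within="cluster", subject="node", between="agent"
        ).set_index("Source")
    return AnovaResult(
        parameter=parameter,
        p_cluster=float(aov.loc["cluster", "p_unc"]),
        p_agent=float(aov.loc["agent", "p_unc"]),
        p_interaction=float(aov.loc["Interaction", "p_unc"]),
        f_cluster=float(aov.loc["cluster", "F"]),
        f_agent=float(aov.loc["agent", "F"]),
        contrasts=contrasts,
    )


def agent_effect(table: pd.DataFrame, parameters: tuple[str, ...] = PARAMETERS) -> pd.DataFrame:
    """Agent main-effect p per parameter (the between-node comparison)."""
    rows = []
    for param in parameters:
        res = two_way_anova(table, param)
        rows.append({"parameter": param, "F_agent": res.f_agent, "p_agent": res.p_agent})
    return pd.DataFrame(rows)


def analyze_all(table: pd.DataFrame) -> dict[str, AnovaResult]:
    """Full analysis of all four parameters."""
    return {param: two_way_anova(table, param) for param in PARAMETERS}


def directional_summary(table: pd.DataFrame) -> dict[str, tuple[int, int]]:
    """Per-node direction counts read straight off the table.

    Returns ``{"auc_inner_gt_outer": (k, n), "washout_inner_le_outer": (k, n),
    "volume_outer_gt_inner": (k, n)}`` where k of n nodes satisfy each
    relation.
    """
    table = validate_param_table(table)
    out = {}
    checks = {
        "auc_inner_gt_outer": ("auc", lambda i, o: i > o),
        "washout_inner_le_outer": ("wash_out", lambda i, o: i <= o),
        "volume_outer_gt_inner": ("volume_pct", lambda i, o: o > i),
    }
    for name, (param, rel) in checks.items():
        wide = table.pivot_table(index="node", columns="cluster", values=param)
        k = int(sum(rel(i, o) for i, o in zip(wide["inner"], wide["outer"])))
        out[name] = (k, len(wide))
    return out


def report_text(results: dict[str, AnovaResult]) -> str:
    """Human-readable summary of the full analysis."""
    lines = ["Cluster and agent comparisons (mixed two-way ANOVA, Bonferroni contrasts)", ""]
    for param, res in results.items():
        lines.append(f"{param}:")
        lines.append(
            f"  cluster main effect: F={res.f_cluster:.2f}, p={res.p_cluster:.4g} "
            f"[{res.significance(res.p_cluster)}]"
        )
        if res.p_agent is not None:
            lines.append(
                f"  agent main effect:   F={res.f_agent:.2f}, p={res.p_agent:.4g} "
                f"[{res.significance(res.p_agent)}]"
            )
        for agent, c in res.contrasts.items():
            lines.append(
                f"  inner-outer ({agent}): diff={c.mean_diff:+.3g}, t({c.df})={c.t:.2f}, "
                f"p_bonf={c.p_bonf:.4g} [{res.significance(c.p_bonf)}]"
            )
        lines.append("")
    return "\n".join(lines)
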