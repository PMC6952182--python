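"""Threshold-based peak-set and gene-set algebra.

Named sets are built from differential-accessibility (DA) and differential-
expression (DE) tables by strict-inequality thresholding (|log2FC| > 0.5 with
FDR < 0.05 for accessibility; the printed thresholds for each expression set)
combined by union/intersection/difference. The module also classifies primed
vs de novo accessible elements against cardiac/pharyngeal-muscle (ASM) gene
programs and tests set intersections for independence with a two-tailed
binomial on the product-of-marginals null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .annotation import PeakGeneMap
from .intervals import Accessome
from .stats import BinomialTestResult, binomial_two_tailed

__all__ = [
    "PeakSet",
    "GeneSet",
    "threshold_select",
    "define_accessibility_sets",
    "define_expression_gene_sets",
    "classify_primed_denovo_elements",
    "intersection_independence_test",
    "summarize_overlap",
]


@dataclass
class PeakSet:
    name: str
    members: set[str]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError(f"peak set {self.name!r} lacks provenance")
        self.members = set(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSet:
    name: str
    members: set[str]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError(f"gene set {self.name!r} lacks provenance")
        self.members = set(self.members)

    def __len__(self) -> int:
        return len(self.members)


def threshold_select(
    table: pd.DataFrame,
    sign: str,
    lfc: float,
    fdr: float | None = 0.05,
    p: float | None = None,
) -> set[str]:
    """IDs passing a strict threshold rule on a DA/DE table.

    ``sign`` is "down" (log2fc < -lfc) or "up" (log2fc > lfc); significance is
    ``fdr`` (strict) or, when ``p`` is given instead, the unadjusted p-value.
    All inequalities are strict, exactly as typeset in the set definitions.
    """
    if sign not in ("up", "down"):
        raise ValueError(f"sign must be 'up' or 'down', got {sign!r}")
    x = table["log2fc"]
    mask = (x > lfc) if sign == "up" else (x < -lfc)
    if p is not None:
        mask &= table["p_value"] < p
    else:
        mask &= table["fdr"] < fdr
    return set(table.index[mask.fillna(False)])


def _need(tables: dict, *names: str) -> None:
    for name in names:
        if name not in tables:
            raise KeyError(f"missing contrast table {name!r}")


def define_accessibility_sets(
    da_tables: dict[str, pd.DataFrame],
    lfc_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
) -> dict[str, PeakSet]:
    """The six named accessibility peak sets.

    Contrast tables are keyed: ``fgfr_dn_vs_control``, ``mek_act_vs_control``,
    ``mek_act_vs_fgfr_dn`` (10 hpf model); ``fgfr_dn_vs_control_18``,
    ``mras_ca_vs_control_18``, ``mras_ca_vs_fgfr_dn_18`` (15-20 hpf model);
    ``control_10_vs_18`` (time model). "Closed in X vs Y" means log2FC < -0.5
    (less accessible in X), "open" means log2FC > 0.5, all with FDR < 0.05.
    """
    t, f = lfc_threshold, fdr_threshold

    def sel(key, sign):
        return threshold_select(da_tables[key], sign, t, f)

    _need(
        da_tables,
        "fgfr_dn_vs_control", "mek_act_vs_control", "mek_act_vs_fgfr_dn",
        "fgfr_dn_vs_control_18", "mras_ca_vs_control_18", "mras_ca_vs_fgfr_dn_18",
        "control_10_vs_18",
    )

    opened_10 = sel("fgfr_dn_vs_control", "down") | sel("mek_act_vs_fgfr_dn", "up")
    closed_10 = sel("mek_act_vs_control", "down") | sel("mek_act_vs_fgfr_dn", "down")
    opened_18 = (
        sel("fgfr_dn_vs_control_18", "down")
        | sel("mras_ca_vs_control_18", "up")
        | sel("mras_ca_vs_fgfr_dn_18", "up")
    )
    closed_18 = (
        sel("fgfr_dn_vs_control_18", "up")
        | sel("mras_ca_vs_control_18", "down")
        | sel("mras_ca_vs_fgfr_dn_18", "down")
    )
    closed_at_10_vs_18 = sel("control_10_vs_18", "down")
    de_novo = closed_at_10_vs_18 - opened_10
    primed = opened_10 - closed_at_10_vs_18

    prov = [f"|log2fc| > {t}, fdr < {f}"]
    return {
        "opened_by_fgf_mapk_10hpf": PeakSet(
            "opened_by_fgf_mapk_10hpf", opened_10,
            prov + ["fgfr_dn_vs_control down OR mek_act_vs_fgfr_dn up"],
        ),
        "closed_by_fgf_mapk_10hpf": PeakSet(
            "closed_by_fgf_mapk_10hpf", closed_10,
            prov + ["mek_act_vs_control down OR mek_act_vs_fgfr_dn down"],
        ),
        "opened_by_fgf_mapk_18hpf": PeakSet(
            "opened_by_fgf_mapk_18hpf", opened_18,
            prov + ["fgfr_dn_vs_control_18 down OR mras_ca up vs control/fgfr_dn"],
        ),
        "closed_by_fgf_mapk_18hpf": PeakSet(
            "closed_by_fgf_mapk_18hpf", closed_18,
            prov + ["fgfr_dn_vs_control_18 up OR mras_ca down vs control/fgfr_dn"],
        ),
        "de_novo": PeakSet(
            "de_novo", de_novo,
            prov + ["control_10_vs_18 down MINUS opened_by_fgf_mapk_10hpf"],
        ),
        "primed": PeakSet(
            "primed", primed,
            prov + ["opened_by_fgf_mapk_10hpf MINUS control_10_vs_18 down"],
        ),
    }


#: (set name, [(table, sign, lfc, fdr, p)], combine) — the printed definitions.
EXPRESSION_SET_RULES: dict[str, dict] = {
    "foxf_targets": {
        "rules": [("foxf_crispr_vs_control", "down", 0.75, 0.05, None)],
        "combine": "intersect",
    },
    "mapk_inhibited_18": {
        "rules": [
            ("mras_ca_vs_control_18", "down", 1.0, 0.05, None),
            ("mras_ca_vs_fgfr_dn_18", "down", 1.0, 0.05, None),
        ],
        "combine": "intersect",
    },
    "mapk_activated_18": {
        "rules": [
            ("fgfr_dn_vs_control_18", "down", 1.0, 0.05, None),
            ("mras_ca_vs_fgfr_dn_18", "up", 1.0, 0.05, None),
        ],
        "combine": "intersect",
    },
    "mapk_activated_10": {
        "rules": [("fgfr_dn_vs_control_10", "down", 1.0, None, 0.05)],
        "combine": "intersect",
    },
    "mapk_inhibited_10": {
        "rules": [("fgfr_dn_vs_control_10", "up", 1.0, None, 0.05)],
        "combine": "intersect",
    },
}


def rules_from_yaml(path) -> dict[str, dict]:
    """Load a threshold-rule grammar from YAML.

    Layout: set name -> {rules: [[comparison, sign, lfc, fdr, p], ...],
    combine: union|intersect|minus}; fdr/p entries may be null.
    """
    import yaml

    payload = yaml.safe_load(open(path))
    out = {}
    for name, spec in payload.items():
        out[name] = {
            "rules": [tuple(rule) for rule in spec["rules"]],
            "combine": spec.get("combine", "intersect"),
        }
    return out


def define_expression_gene_sets(
    de_tables: dict[str, pd.DataFrame],
    rules: dict[str, dict] | None = None,
) -> dict[str, GeneSet]:
    """Build the named expression gene sets (and any user-defined rules).

    Each rule is (comparison table, sign, |log2fc| threshold, fdr threshold or
    None, raw-p threshold or None); rules combine by union/intersect/minus.
    """
    rules = dict(EXPRESSION_SET_RULES if rules is None else rules)
    out: dict[str, GeneSet] = {}
    for name, spec in rules.items():
        parts = []
        prov = []
        for table_name, sign, lfc, fdr, p in spec["rules"]:
            if table_name not in de_tables:
                raise KeyError(f"unknown comparison {table_name!r} for set {name!r}")
            table = de_tables[table_name]
            if table.empty:
                warnings.warn(f"empty DE table {table_name!r}; set {name!r} may be empty")
            parts.append(threshold_select(table, sign, lfc, fdr, p))
            prov.append(f"{table_name}:{sign}:lfc>{lfc}:" + (f"p<{p}" if p else f"fdr<{fdr}"))
        combine = spec.get("combine", "intersect")
        if combine == "union":
            members = set().union(*parts)
        elif combine == "intersect":
            members = set.intersection(*parts)
        elif combine == "minus":
            members = parts[0].difference(*parts[1:]) if parts else set()
        else:
            raise ValueError(f"unknown combine mode {combine!r}")
        out[name] = GeneSet(name, members, prov + [f"combine={combine}"])
    return out


def classify_primed_denovo_elements(
    peak_gene_map: PeakGeneMap,
    da_tables: dict[str, pd.DataFrame],
    gene_sets: dict[str, GeneSet],
    peak_sets: dict[str, PeakSet],
) -> dict[str, PeakSet]:
    """Primed/de novo elements split by cardiac vs pharyngeal-muscle programs.

    An element associated with a de novo cardiac gene is cardiac-accessible if
    log2FC < 0 in mras_ca_vs_control_18 or log2FC > 0 in fgfr_dn_vs_control_18
    (strict signs); ASM-accessible uses the opposite signs against de novo ASM
    genes. ASM elements also associated with a cardiac or MAPK-inhibited-18hpf
    gene are removed; cardiac elements also associated with an ASM or
    MAPK-activated-18hpf gene are removed.
    """
    for key in ("de_novo", "primed"):
        if key not in peak_sets:
            raise KeyError(f"missing prerequisite peak set {key!r}")
    for key in ("denovo_cardiac", "denovo_asm"):
        if key not in gene_sets:
            raise KeyError(f"missing prerequisite gene set {key!r}")
    _need(da_tables, "mras_ca_vs_control_18", "fgfr_dn_vs_control_18")

    mras = da_tables["mras_ca_vs_control_18"]["log2fc"]
    fgfr = da_tables["fgfr_dn_vs_control_18"]["log2fc"]

    def cardiac_sign(pid):
        return (mras.get(pid, 0) < 0) or (fgfr.get(pid, 0) > 0)

    def asm_sign(pid):
        return (mras.get(pid, 0) > 0) or (fgfr.get(pid, 0) < 0)

    p2g = peak_gene_map.peak_to_genes()
    cardiac_genes = gene_sets["denovo_cardiac"].members
    asm_genes = gene_sets["denovo_asm"].members
    mapk_inh = gene_sets.get("mapk_inhibited_18", GeneSet("x", set(), ["none"])).members
    mapk_act = gene_sets.get("mapk_activated_18", GeneSet("x", set(), ["none"])).members

    out: dict[str, PeakSet] = {}
    for kind in ("primed", "de_novo"):
        pool = peak_sets[kind].members
        cardiac = {
            pid for pid in pool
            if p2g.get(pid, set()) & cardiac_genes and cardiac_sign(pid)
        }
        asm = {
            pid for pid in pool
            if p2g.get(pid, set()) & asm_genes and asm_sign(pid)
        }
        cardiac = {
            pid for pid in cardiac
            if not (p2g.get(pid, set()) & (asm_genes | mapk_act))
        }
        asm = {
            pid for pid in asm
            if not (p2g.get(pid, set()) & (cardiac_genes | mapk_inh))
        }
        tag = "primed" if kind == "primed" else "denovo"
        out[f"{tag}_cardiac_accessible"] = PeakSet(
            f"{tag}_cardiac_accessible", cardiac,
            [f"{kind} elements near denovo_cardiac genes, cardiac 18 hpf sign, exclusions applied"],
        )
        out[f"{tag}_asm_accessible"] = PeakSet(
            f"{tag}_asm_accessible", asm,
            [f"{kind} elements near denovo_asm genes, ASM 18 hpf sign, exclusions applied"],
        )
    return out


def intersection_independence_test(
    sets: list[PeakSet], universe: Accessome | set[str], min_sets: int = 1
) -> pd.DataFrame:
    """Two-tailed binomial test of each intersection pattern vs independence.

    For every combination of >= ``min_sets`` input sets, the null probability
    is the product of the constituent set fractions of the universe; observed
    k is the intersection size and n the universe size.
    """
    if isinstance(universe, Accessome):
        universe_ids = set(universe.peak_ids)
    else:
        universe_ids = set(universe)
    n = len(universe_ids)
    if n == 0:
        raise ValueError("empty universe")
    for s in sets:
        if not s.members <= universe_ids:
            raise ValueError(f"set {s.name!r} not contained in the universe")
    rows = []
    for r in range(min_sets, len(sets) + 1):
        for combo in combinations(sets, r):
            p0 = 1.0
            inter = universe_ids
            for s in combo:
                p0 *= len(s) / n
                inter = inter & s.members
            k = len(inter)
            if 0 < p0 < 1:
                res = binomial_two_tailed(k, n, p0)
                p_value, direction = res.p_value, res.direction
            else:  # degenerate: an empty or universe-sized constituent
                p_value, direction = 1.0, "under"
            rows.append(
                ("&".join(s.name for s in combo), k, n, p0, p_value, direction)
            )
    return pd.DataFrame(
        rows, columns=["intersection", "k", "n", "p0", "p_value", "direction"]
    )


def summarize_overlap(a, b) -> dict[str, float]:
    """|a intersect b|, |a| and the percentage 100*|a&b|/|a| (one decimal)."""
    members_a = a.members if hasattr(a, "members") else set(a)
    members_b = b.members if hasattr(b, "members") else set(b)
    if not members_a:
        raise ValueError("overlap percentage undefined for an empty reference set")
    inter = len(members_a & members_b)
    return {
        "intersection": inter,
        "size": len(members_a),
        "percentage": round(100.0 * inter / len(members_a), 1),
    }
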