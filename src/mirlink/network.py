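"""Bipartite miRNA->mRNA regulatory network analysis.

Builds the bipartite graph from significance-filtered pairs, summarises
out-degrees (targets per miRNA) and in-degrees (regulators per mRNA), fits
the degree-frequency distributions (power law on log-log, exponential on
log-linear), and extracts coregulatory modules: groups of >= 2 miRNAs
connected through shared target mRNAs.

A packaged fixture transcribes the drought-network edge list of the study
this pipeline re-implements (13 miRNAs, their response direction and target
lists).  Note the printed table is internally inconsistent: the stated
per-miRNA target counts sum to 67 (text claims 69 regulations) while the
printed name lists contain 66 entries over 57 unique targets (one row lists
8 names against a stated 9).  The fixture preserves both representations.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd


class NetworkError(ValueError):
    pass


class FixtureError(RuntimeError):
    """Packaged fixture missing or corrupted."""


_TABLE1_SHA256 = "9a431391d990817b1f7eba26b1b8a51635b24003f29dff49fb1ad5ddcf339eaa"


@dataclass
class RegulatoryNetwork:
    """Bipartite miRNA->mRNA graph with optional edge scores/directions."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    mirna_response: dict[str, str] = field(default_factory=dict)  # up | down

    @property
    def mirnas(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("kind") == "mirna"
        )

    @property
    def mrnas(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("kind") == "mrna"
        )

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def targets_of(self, mirna_id: str) -> set[str]:
        return set(self.graph.neighbors(mirna_id))

    def add_edge(self, mirna_id: str, mrna_id: str, score: float | None = None) -> None:
        if self.graph.nodes.get(mirna_id, {}).get("kind") == "mrna":
            raise NetworkError(f"{mirna_id!r} already present as an mRNA node")
        if self.graph.nodes.get(mrna_id, {}).get("kind") == "mirna":
            raise NetworkError(f"{mrna_id!r} already present as a miRNA node")
        if mirna_id == mrna_id:
            raise NetworkError(f"{mirna_id!r} cannot appear on both sides")
        self.graph.add_node(mirna_id, kind="mirna", bipartite=0)
        self.graph.add_node(mrna_id, kind="mrna", bipartite=1)
        attrs = {} if score is None else {"score": float(score)}
        self.graph.add_edge(mirna_id, mrna_id, **attrs)

    # -- export ----------------------------------------------------------
    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v, d in self.graph.edges(data=True):
            mirna, mrna = (u, v) if self.graph.nodes[u]["kind"] == "mirna" else (v, u)
            rows.append(
                {
                    "mirna_id": mirna,
                    "mrna_id": mrna,
                    "score": d.get("score", np.nan),
                    "response": self.mirna_response.get(mirna, ""),
                }
            )
        return pd.DataFrame(rows).sort_values(["mirna_id", "mrna_id"]).reset_index(drop=True)

    def to_sif(self, path, interaction: str = "represses") -> None:
        with open(path, "w") as fh:
            for _, row in self.edge_table().iterrows():
                fh.write(f"{row.mirna_id}\t{interaction}\t{row.mrna_id}\n")

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(significant_pairs) -> RegulatoryNetwork:
    """Bipartite network from significance-filtered pairs.

    Accepts a DataFrame with mirna_id/mrna_id (and optional score) columns
    or an iterable of (mirna_id, mrna_id[, score]) tuples.  Duplicate pairs
    collapse to one edge.
    """
    net = RegulatoryNetwork()
    if isinstance(significant_pairs, pd.DataFrame):
        records = significant_pairs.to_dict("records")
        for row in records:
            net.add_edge(row["mirna_id"], row["mrna_id"], row.get("score"))
    else:
        for item in significant_pairs:
            net.add_edge(item[0], item[1], item[2] if len(item) > 2 else None)
    return net


def degree_summary(net: RegulatoryNetwork) -> tuple[pd.Series, pd.Series]:
    """(out-degree per miRNA, in-degree per mRNA)."""
    out_deg = pd.Series(
        {m: net.graph.degree(m) for m in net.mirnas}, dtype=int, name="out_degree"
    )
    in_deg = pd.Series(
        {g: net.graph.degree(g) for g in net.mrnas}, dtype=int, name="in_degree"
    )
    return out_deg, in_deg


@dataclass
class DegreeFit:
    model: str                   # "power_law" | "exponential"
    slope_or_exponent: float
    intercept: float
    r_squared: float
    points_used: list[tuple[int, int]]  # (degree, frequency)


def fit_degree_distribution(degrees, model: str) -> DegreeFit:
    """Linearised OLS fit of the degree-frequency distribution.

    power_law: log10(freq) ~ log10(degree); exponential: log10(freq) ~ degree.
    Zero-frequency degrees are absent by construction; requires >= 3
    distinct degree values.
    """
    if model not in ("power_law", "exponential"):
        raise NetworkError(f"unknown model {model!r}")
    counts = pd.Series(list(degrees)).value_counts().sort_index()
    counts = counts[counts.index > 0]
    if len(counts) < 3:
        raise NetworkError("need >= 3 distinct degree values to fit")
    deg = counts.index.to_numpy(dtype=float)
    freq = counts.to_numpy(dtype=float)
    x = np.log10(deg) if model == "power_law" else deg
    y = np.log10(freq)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = ((y - fitted) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DegreeFit(
        model=model,
        slope_or_exponent=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        points_used=[(int(d), int(f)) for d, f in zip(deg, freq)],
    )


@dataclass
class Module:
    mirna_ids: list[str]
    shared_mrna_ids: list[str]


@dataclass
class ModuleSet:
    modules: list[Module]

    def __len__(self) -> int:
        return len(self.modules)


def find_modules(net: RegulatoryNetwork) -> ModuleSet:
    """Coregulatory modules: connected components of the shared-target
    projection with >= 2 miRNAs.

    Two miRNAs are linked when they share at least one target; each module
    reports the targets shared by at least two of its miRNAs.
    """
    proj = nx.Graph()
    mirnas = net.mirnas
    proj.add_nodes_from(mirnas)
    for i, a in enumerate(mirnas):
        ta = net.targets_of(a)
        for b in mirnas[i + 1 :]:
            if ta & net.targets_of(b):
                proj.add_edge(a, b)
    modules = []
    for comp in nx.connected_components(proj):
        if len(comp) < 2:
            continue
        members = sorted(comp)
        shared: set[str] = set()
        for i, a in enumerate(members):
            ta = net.targets_of(a)
            for b in members[i + 1 :]:
                shared |= ta & net.targets_of(b)
        modules.append(Module(mirna_ids=members, shared_mrna_ids=sorted(shared)))
    modules.sort(key=lambda m: m.mirna_ids)
    return ModuleSet(modules)


def coregulated_fraction(net: RegulatoryNetwork) -> float:
    """Fraction of mRNA nodes regulated by >= 2 miRNAs."""
    _, in_deg = degree_summary(net)
    if len(in_deg) == 0:
        raise NetworkError("empty network")
    return float((in_deg >= 2).mean())


# ---------------------------------------------------------------------------
# Packaged fixture
# ---------------------------------------------------------------------------

def _read_fixture(name: str, sha256: str) -> str:
    ref = resources.files("mirlink.data").joinpath(name)
    try:
        text = ref.read_text()
    except FileNotFoundError as exc:
        raise FixtureError(f"fixture {name} missing") from exc
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != sha256:
        raise FixtureError(f"fixture {name} checksum mismatch: {digest}")
    return text


def table1_table() -> pd.DataFrame:
    """The fixture edge list verbatim: one row per miRNA with its family,
    response direction, stated target count and printed target names."""
    import io

    text = _read_fixture("table1_edges.tsv", _TABLE1_SHA256)
    frame = pd.read_csv(io.StringIO(text), sep="\t")
    frame["targets"] = frame["targets"].str.split(",")
    return frame


def load_table1_fixture() -> RegulatoryNetwork:
    """The drought regulatory network from the printed per-miRNA target
    lists (66 printed edges over 13 miRNAs and 57 unique targets)."""
    frame = table1_table()
    net = RegulatoryNetwork()
    for _, row in frame.iterrows():
        for target in row["targets"]:
            net.add_edge(row["mirna"], target)
        net.mirna_response[row["mirna"]] = row["response"].lower()
    return net
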