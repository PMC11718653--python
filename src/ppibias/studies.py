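"""Study catalogs: reading, aggregation, and synthetic generation.

A study catalog is a collection of single-study PPI networks with bait/prey
role annotations.  Catalogs can be read from PSI-MITAB 2.5/2.7 files (the
format distributed by IntAct) or from a simple 4-column TSV, aggregated into
one undirected network with per-edge provenance and per-protein bait-usage
counts, and — for download-free experiments — generated synthetically with
the descriptive features of real catalogs: long-tailed study sizes,
asymmetric bait/prey designs, power-law-distributed research interest with a
point mass of never-tested proteins, and a per-test error model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import networkx as nx
import numpy as np

from .analytic import BaitUsage
from .correction import RoleAnnotatedStudy
from .powerlaw import (
    EstimationError,
    GoFResult,
    _DiscretePLSampler,
    bootstrap_gof,
    fit_discrete_pl,
)

__all__ = [
    "StudyCatalog",
    "AggregatedNetwork",
    "read_mitab_lite",
    "read_catalog_tsv",
    "write_catalog_tsv",
    "aggregate",
    "merge_random_subsets",
    "synthetic_catalog",
    "draw_study_sizes",
]

logger = logging.getLogger(__name__)

_MI_BAIT = "MI:0496"
_MI_PREY = "MI:0498"


@dataclass
class StudyCatalog:
    """A list of role-annotated studies, optionally restricted to a protein whitelist."""

    studies: list = field(default_factory=list)
    protein_universe: set | None = None

    def __post_init__(self):
        ids = [s.study_id for s in self.studies]
        if len(ids) != len(set(ids)):
            raise ValueError("study ids must be unique")
        if self.protein_universe is not None:
            self.studies = [_restrict(s, self.protein_universe) for s in self.studies]

    def __len__(self):
        return len(self.studies)


def _restrict(study: RoleAnnotatedStudy, universe: set) -> RoleAnnotatedStudy:
    return RoleAnnotatedStudy(
        study_id=study.study_id,
        interactions=[
            (b, p) for b, p in study.interactions if b in universe and p in universe
        ],
        method=study.method,
        unoriented=[
            (a, b) for a, b in study.unoriented if a in universe and b in universe
        ],
    )


@dataclass
class AggregatedNetwork:
    """Union of many single-study networks with provenance and bait usage."""

    graph: nx.Graph
    provenance: dict  # frozenset edge -> set of study ids
    bait_usage: BaitUsage


def _primary_id(raw: str) -> str:
    # "uniprotkb:P12345" -> "P12345"; plain identifiers pass through
    return raw.split(":", 1)[1] if ":" in raw else raw


def read_mitab_lite(path) -> StudyCatalog:
    """Parse a PSI-MITAB 2.5+ file into a study catalog.

    Interprets interactor identifiers (columns 1-2), the detection method
    (column 7), the publication identifier (column 9, used as study id) and
    the experimental roles (columns 17-18; bait MI:0496, prey MI:0498).
    Records without role terms are kept as unoriented; malformed lines and
    self-interactions are skipped with logged counts.
    """
    per_study: dict[str, RoleAnnotatedStudy] = {}
    n_bad = n_self = n_unroled = 0
    n_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                n_bad += 1
                continue
            n_lines += 1
            id_a, id_b = _primary_id(cols[0]), _primary_id(cols[1])
            method = cols[6]
            study_id = cols[8] if cols[8] and cols[8] != "-" else "unknown"
            if id_a == id_b:
                n_self += 1
                continue
            study = per_study.setdefault(
                study_id, RoleAnnotatedStudy(study_id=study_id, method=method)
            )
            role_a = cols[16] if len(cols) > 16 else ""
            role_b = cols[17] if len(cols) > 17 else ""
            a_is_bait = _MI_BAIT in role_a
            b_is_bait = _MI_BAIT in role_b
            a_is_prey = _MI_PREY in role_a
            b_is_prey = _MI_PREY in role_b
            if a_is_bait and b_is_prey:
                study.interactions.append((id_a, id_b))
            elif b_is_bait and a_is_prey:
                study.interactions.append((id_b, id_a))
            else:
                n_unroled += 1
                study.unoriented.append((id_a, id_b))
    if n_bad or n_self or n_unroled:
        logger.warning(
            "read_mitab_lite: skipped %d malformed line(s), %d self-interaction(s); "
            "%d record(s) without bait/prey roles kept as unoriented",
            n_bad,
            n_self,
            n_unroled,
        )
    if n_lines == 0:
        raise ValueError(f"no parseable MITAB lines in {path}")
    # de-duplicate via the dataclass invariant
    studies = [
        RoleAnnotatedStudy(s.study_id, s.interactions, s.method, s.unoriented)
        for s in per_study.values()
    ]
    return StudyCatalog(studies=studies)


def write_catalog_tsv(catalog: StudyCatalog, path) -> None:
    """Write the 4-column role-annotated TSV (study_id, bait, prey, method).

    Unoriented records are written with role placeholders preserved by the
    reader through the reserved method suffix ``/unoriented``.
    """
    with open(path, "w") as fh:
        fh.write("study_id\tbait\tprey\tmethod\n")
        for s in catalog.studies:
            for b, p in s.interactions:
                fh.write(f"{s.study_id}\t{b}\t{p}\t{s.method}\n")
            for a, b in s.unoriented:
                fh.write(f"{s.study_id}\t{a}\t{b}\t{s.method}/unoriented\n")


def read_catalog_tsv(path) -> StudyCatalog:
    """Read the 4-column role-annotated TSV written by :func:`write_catalog_tsv`."""
    per_study: dict[str, RoleAnnotatedStudy] = {}
    with open(path) as fh:
        header = next(fh, "")
        if not header.startswith("study_id"):
            raise ValueError("expected a header line starting with 'study_id'")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            study_id, bait, prey, method = line.split("\t")[:4]
            unoriented = method.endswith("/unoriented")
            study = per_study.setdefault(
                study_id,
                RoleAnnotatedStudy(
                    study_id=study_id, method=method.removesuffix("/unoriented")
                ),
            )
            if unoriented:
                study.unoriented.append((bait, prey))
            else:
                study.interactions.append((bait, prey))
    studies = [
        RoleAnnotatedStudy(s.study_id, s.interactions, s.method, s.unoriented)
        for s in per_study.values()
    ]
    return StudyCatalog(studies=studies)


def aggregate(catalog: StudyCatalog) -> AggregatedNetwork:
    """Union of all studies' unique undirected interactions.

    ``bait_usage[u]`` counts the number of studies in which ``u`` appears at
    least once as a bait (within-study repetition is not distinguishable in
    MITAB and counts once).
    """
    if not catalog.studies:
        raise ValueError("catalog is empty")
    g = nx.Graph()
    provenance: dict[frozenset, set] = {}
    usage: dict[Hashable, int] = {}
    for s in catalog.studies:
        for u in s.proteins:
            g.add_node(u)
        for e in s.edges:
            u, v = tuple(e)
            g.add_edge(u, v)
            provenance.setdefault(e, set()).add(s.study_id)
        for u in s.baits:
            usage[u] = usage.get(u, 0) + 1
    for u in g.nodes():
        usage.setdefault(u, 0)
    return AggregatedNetwork(graph=g, provenance=provenance, bait_usage=BaitUsage(usage))


def merge_random_subsets(
    catalog: StudyCatalog,
    subset_size: int,
    reps: int,
    seed,
    n_boot: int = 100,
) -> list[GoFResult]:
    """Aggregate random study subsets and test each merged degree distribution
    for power-law plausibility.

    Each repetition samples ``subset_size`` studies without replacement,
    aggregates them, fits the discrete power law to the degree sequence and
    runs the bootstrap GoF test.  Repetitions where the fit itself fails are
    returned as invalid results with ``n_failed = n_boot``.
    """
    if reps < 1:
        raise ValueError("reps must be positive")
    if not 1 <= subset_size <= len(catalog.studies):
        raise ValueError("subset_size must be in [1, number of studies]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    results = []
    for _ in range(reps):
        idx = rng.choice(len(catalog.studies), size=subset_size, replace=False)
        sub = StudyCatalog(studies=[catalog.studies[i] for i in sorted(idx)])
        agg = aggregate(sub)
        degrees = [d for _, d in agg.graph.degree()]
        try:
            fit = fit_discrete_pl(degrees)
        except EstimationError:
            results.append(
                GoFResult(
                    p_value=0.0,
                    n_boot=n_boot,
                    n_failed=n_boot,
                    valid=False,
                    plausible=False,
                )
            )
            continue
        results.append(bootstrap_gof(degrees, fit, n_boot=n_boot, seed=rng))
    return results


def draw_study_sizes(
    n_experiments: int,
    n_proteins: int,
    seed,
    method: str = "AP-MS",
    size_alpha: float = 2.5,
    min_balance: float = 0.02,
) -> list[tuple[int, int]]:
    """Draw (n_bait, n_prey) per study: long-tailed bait counts and a
    log-uniform size balance spanning symmetric to highly asymmetric designs.

    Bait counts follow a discrete power law with exponent ``size_alpha``
    (most studies have very few baits), capped at a tenth of the proteome;
    the prey count is the bait count divided by a balance drawn log-uniformly
    from [``min_balance``, 1], capped at the proteome size.  In Y2H mode bait
    and prey counts are drawn the same way (both are actively selected).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cap = max(1, n_proteins // 10)
    sampler = _DiscretePLSampler(size_alpha, 1)
    n_bait = np.minimum(sampler.sample(n_experiments, rng), cap)
    balance = 10.0 ** rng.uniform(np.log10(min_balance), 0.0, size=n_experiments)
    n_prey = np.minimum(
        np.maximum(np.round(n_bait / balance).astype(np.int64), n_bait), n_proteins
    )
    return list(zip(n_bait.tolist(), n_prey.tolist()))


def synthetic_catalog(
    n_proteins: int,
    n_studies: int,
    fpr: float,
    fnr: float,
    ground_truth: nx.Graph,
    seed,
    bias_alpha: float = 3.13,
    zero_frac: float = 0.24,
    method: str = "AP-MS",
    size_alpha: float = 2.5,
    min_balance: float = 0.02,
) -> StudyCatalog:
    """Generate a synthetic study catalog emulating real-catalog statistics.

    Each protein receives a research-interest weight: zero with probability
    ``zero_frac`` (never selected as bait), otherwise a draw from the discrete
    power law with exponent ``bias_alpha``.  Per study, (n_bait, n_prey) come
    from :func:`draw_study_sizes`; baits are sampled without replacement
    proportional to interest, preys uniformly (AP-MS) or proportional to
    interest (Y2H); every bait x prey pair is tested once against
    ``ground_truth`` with the per-test error model, and positive tests are
    emitted as (bait, prey) interaction records.  Studies with no positive
    test stay in the catalog as empty studies.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = list(ground_truth.nodes())
    if len(nodes) != n_proteins:
        raise ValueError("ground_truth must have exactly n_proteins nodes")
    interest = np.zeros(n_proteins)
    tested = rng.random(n_proteins) >= zero_frac
    k = int(tested.sum())
    if k == 0:
        raise ValueError("zero_frac leaves no testable protein")
    interest[tested] = _DiscretePLSampler(bias_alpha, 1).sample(k, rng)
    testable = np.nonzero(tested)[0]

    sizes = draw_study_sizes(
        n_studies, n_proteins, rng, method=method, size_alpha=size_alpha, min_balance=min_balance
    )
    node_index = {u: i for i, u in enumerate(nodes)}
    gt_codes = np.sort(
        np.array(
            [
                min(node_index[u], node_index[v]) * n_proteins
                + max(node_index[u], node_index[v])
                for u, v in ground_truth.edges()
            ],
            dtype=np.int64,
        )
    )
    studies = []
    w = interest[testable]
    for i, (n_bait, n_prey) in enumerate(sizes):
        n_bait = min(n_bait, testable.size)
        keys = rng.exponential(size=w.size) / w
        baits_idx = (
            testable[np.argpartition(keys, n_bait - 1)[:n_bait]]
            if n_bait < w.size
            else testable
        )
        if method == "Y2H":
            keys_p = rng.exponential(size=w.size) / w
            n_prey_eff = min(n_prey, testable.size)
            preys_idx = testable[np.argpartition(keys_p, n_prey_eff - 1)[:n_prey_eff]]
        else:
            preys_idx = rng.permutation(n_proteins)[:n_prey]
        iu = np.repeat(baits_idx, preys_idx.size)
        iv = np.tile(preys_idx, baits_idx.size)
        keep = iu != iv
        iu, iv = iu[keep], iv[keep]
        codes = np.minimum(iu, iv) * n_proteins + np.maximum(iu, iv)
        is_edge = np.isin(codes, gt_codes)
        pos = rng.random(iu.size) < np.where(is_edge, 1.0 - fnr, fpr)
        interactions = [(nodes[a], nodes[b]) for a, b in zip(iu[pos].tolist(), iv[pos].tolist())]
        studies.append(
            RoleAnnotatedStudy(study_id=f"S{i:05d}", interactions=interactions, method=method)
        )
    return StudyCatalog(studies=studies)
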