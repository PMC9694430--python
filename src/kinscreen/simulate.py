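"""Synthetic data: melt curves, whole screens with ground truth, kinome tables.

The generators emulate the study conditions of a kinase chemogenomic DSF
screen — a 25-95 degC ramp at 0.5 degC sampling, sigmoidal unfolding with
post-peak fluorescence decay, triplicate wells, per-kinase DMSO controls, a
40-kinase x 627-compound panel with a heavy-tailed compound promiscuity
structure, and a 1467-gene kinome annotated into 63 families with 21
expression libraries.  Planted ground truth (true shifts, planted expressed /
network-selected gene sets) is returned alongside the data so every pipeline
stage can be checked against what was actually put in.

Noise model for screen-level Tm values: replicate wells of one
(kinase, compound) condition share a condition-level Gaussian deviation
(``tm_noise_sd``) plus a small independent per-well jitter
(``replicate_jitter_sd``).  Same-plate replicates of the same mixture drift
together — protein batch and compound aliquot are shared — so the dominant
variance sits at the condition level.  Each DMSO control well is its own
condition.  Under this model the replicate-mean shift of an inert compound
has essentially the same SD as a single control well, which is what makes the
2x-SD hit threshold behave like a one-sided 2-sigma test (~2.3% false
positives).

All generators are pure functions of (parameters, seed): a single root seed
fans out to keyed substreams so any subset regenerates identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from ._util import substream
from .errors import MalformedInputError
from .melt import DMSO, MeltCurve, boltzmann


@dataclass(frozen=True)
class CurveParams:
    """Physics of one simulated melt trace.

    ``decay_onset`` degrees above the melting point the signal starts an
    exponential decay with scale ``decay_tau`` (dye leaving aggregates);
    ``math.inf`` disables the decay.
    """

    f_pre: float = 100.0
    f_post: float = 1000.0
    tm_true: float = 55.0
    slope_true: float = 2.5
    decay_onset: float = 5.0
    decay_tau: float = 15.0
    noise_sd: float = 10.0
    t_start: float = 25.0
    t_end: float = 95.0
    t_step: float = 0.5

    def __post_init__(self):
        if self.f_post <= self.f_pre:
            raise MalformedInputError("f_post must exceed f_pre")
        if self.slope_true <= 0 or self.t_step <= 0 or self.decay_tau <= 0:
            raise MalformedInputError("slope_true, t_step and decay_tau must be positive")
        if self.t_start >= self.t_end:
            raise MalformedInputError("t_start must be below t_end")
        if self.noise_sd < 0:
            raise MalformedInputError("noise_sd must be >= 0")

    @property
    def temperatures(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.t_step)) + 1
        return self.t_start + self.t_step * np.arange(n)


def simulate_curve(
    params: CurveParams,
    seed: int | np.random.Generator,
    plate_id: str = "sim-plate",
    well_id: str = "A01",
    kinase_id: str = "KIN",
    compound_id: str = DMSO,
    replicate: int = 1,
) -> MeltCurve:
    """One melt trace: Boltzmann sigmoid x exponential post-peak decay + noise."""
    rng = seed if isinstance(seed, np.random.Generator) else substream(int(seed))
    t = params.temperatures
    signal = boltzmann(t, params.f_pre, params.f_post, params.tm_true, params.slope_true)
    onset = params.tm_true + params.decay_onset
    if math.isfinite(onset):
        signal = signal * np.exp(-np.maximum(0.0, t - onset) / params.decay_tau)
    if params.noise_sd > 0:
        signal = signal + rng.normal(0.0, params.noise_sd, size=t.shape)
    return MeltCurve(
        plate_id=plate_id,
        well_id=well_id,
        kinase_id=kinase_id,
        compound_id=compound_id,
        replicate=replicate,
        temperatures=t,
        fluorescence=signal,
    )


@dataclass(frozen=True)
class ScreenScenario:
    """Shape and effect structure of a simulated screen.

    Defaults mirror the screened panel (40 kinases x 627 compounds, wells in
    triplicate, two control columns of DMSO wells per kinase).  Compound
    promiscuity is heavy-tailed: a small fraction of compounds
    (``binder_tail_fraction``) binds a large random share of the panel while
    the rest bind almost nothing, giving the characteristic many-zero /
    few-promiscuous histogram.  True shifts of binders are uniform on
    ``shift_range`` degC.
    """

    n_kinases: int = 40
    n_compounds: int = 627
    n_replicates: int = 3
    n_dmso_wells: int = 16
    tm_noise_sd: float = 0.3
    replicate_jitter_sd: float = 0.05
    base_tm_range: tuple[float, float] = (45.0, 60.0)
    binder_tail_fraction: float = 0.032
    tail_prob_range: tuple[float, float] = (0.3, 0.8)
    body_prob_range: tuple[float, float] = (0.0, 0.025)
    shift_range: tuple[float, float] = (1.0, 8.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_kinases", "n_compounds", "n_replicates", "n_dmso_wells"):
            if getattr(self, name) <= 0:
                raise MalformedInputError(f"{name} must be positive")
        if self.n_dmso_wells < 2:
            raise MalformedInputError("n_dmso_wells must be >= 2 (reference needs 2 wells)")
        if not 0.0 <= self.binder_tail_fraction <= 1.0:
            raise MalformedInputError("binder_tail_fraction must lie in [0, 1]")
        for lo, hi in (self.tail_prob_range, self.body_prob_range):
            if not 0.0 <= lo <= hi <= 1.0:
                raise MalformedInputError("binding probability ranges must lie in [0, 1]")
        if self.tm_noise_sd < 0 or self.replicate_jitter_sd < 0:
            raise MalformedInputError("noise SDs must be >= 0")


@dataclass(frozen=True)
class ScreenSim:
    """Simulated screen: per-well Tm values plus the planted ground truth."""

    scenario: ScreenScenario
    wells: pd.DataFrame  # plate_id, well_id, kinase_id, compound_id, replicate, tm_c
    truth: pd.DataFrame  # kinase_id, compound_id, true_shift_c

    def to_fit_table(self) -> pd.DataFrame:
        """Dress the well Tm values as an all-passing per-well fit table.

        Useful for exercising the screen stage without rendering and fitting
        tens of thousands of fluorescence traces.
        """
        df = self.wells.copy()
        df["slope_c"] = 2.5
        df["f_pre"] = 100.0
        df["f_post"] = 1000.0
        df["r_squared"] = 1.0
        df["rmse"] = 0.0
        df["converged"] = True
        df["qc"] = "pass"
        df["qc_reasons"] = ""
        return df


def simulate_screen(scenario: ScreenScenario = ScreenScenario()) -> ScreenSim:
    """Generate well-level Tm data and ground truth for a whole screen."""
    s = scenario
    kinases = [f"K{i:03d}" for i in range(s.n_kinases)]
    compounds = [f"C{j:04d}" for j in range(s.n_compounds)]

    rng_global = substream(s.seed, 0)
    base_tm = rng_global.uniform(*s.base_tm_range, size=s.n_kinases)

    # Per-compound binding probability: promiscuous tail vs near-inert body.
    rng_cmp = substream(s.seed, 1)
    is_tail = rng_cmp.random(s.n_compounds) < s.binder_tail_fraction
    p = np.where(
        is_tail,
        rng_cmp.uniform(*s.tail_prob_range, size=s.n_compounds),
        rng_cmp.uniform(*s.body_prob_range, size=s.n_compounds),
    )

    well_rows = []
    truth_rows = []
    for ki, kinase in enumerate(kinases):
        rng = substream(s.seed, 2, ki)
        binds = rng.random(s.n_compounds) < p
        shifts = np.where(binds, rng.uniform(*s.shift_range, size=s.n_compounds), 0.0)
        cond_noise = rng.normal(0.0, s.tm_noise_sd, size=s.n_compounds)
        jitter = rng.normal(0.0, s.replicate_jitter_sd, size=(s.n_compounds, s.n_replicates))
        plate = f"plate-{ki:03d}"
        well = 0
        for cj, compound in enumerate(compounds):
            truth_rows.append((kinase, compound, float(shifts[cj])))
            for rep in range(s.n_replicates):
                well += 1
                tm = base_tm[ki] + shifts[cj] + cond_noise[cj] + jitter[cj, rep]
                well_rows.append((plate, f"W{well:05d}", kinase, compound, rep + 1, float(tm)))
        dmso_noise = rng.normal(
            0.0,
            math.hypot(s.tm_noise_sd, s.replicate_jitter_sd),
            size=s.n_dmso_wells,
        )
        for d in range(s.n_dmso_wells):
            well += 1
            well_rows.append(
                (plate, f"W{well:05d}", kinase, DMSO, d + 1, float(base_tm[ki] + dmso_noise[d]))
            )

    wells = pd.DataFrame(
        well_rows,
        columns=["plate_id", "well_id", "kinase_id", "compound_id", "replicate", "tm_c"],
    )
    truth = pd.DataFrame(truth_rows, columns=["kinase_id", "compound_id", "true_shift_c"])
    return ScreenSim(scenario=s, wells=wells, truth=truth)


def wells_to_curves(
    wells: pd.DataFrame,
    params: CurveParams = CurveParams(),
    seed: int = 0,
) -> Iterator[MeltCurve]:
    """Render each well of a simulated screen as a full fluorescence trace.

    The well's Tm becomes the sigmoid midpoint; fluorescence noise comes from
    a per-well substream keyed by row position, so any subset of wells
    regenerates identically.
    """
    for idx, row in enumerate(wells.itertuples(index=False)):
        rng = substream(seed, 3, idx)
        yield simulate_curve(
            replace(params, tm_true=float(row.tm_c)),
            rng,
            plate_id=row.plate_id,
            well_id=row.well_id,
            kinase_id=row.kinase_id,
            compound_id=row.compound_id,
            replicate=int(row.replicate),
        )


# --- kinome tables ----------------------------------------------------------


@dataclass(frozen=True)
class KinomeScenario:
    """Shape of the simulated kinome annotation (counts are planted exactly)."""

    n_genes: int = 1467
    n_families: int = 63
    n_libraries: int = 21
    n_expressed: int = 975
    n_network: int = 141
    n_network_families: int = 45
    n_curated: int = 3
    n_lacking_domain: int = 15
    n_synthesis_failed: int = 18
    seed: int = 0

    def __post_init__(self):
        if min(self.n_genes, self.n_families, self.n_libraries) <= 0:
            raise MalformedInputError("counts must be positive")
        if self.n_expressed < 2 * self.n_families:
            raise MalformedInputError("need at least two expressed genes per family")
        if self.n_expressed > self.n_genes:
            raise MalformedInputError("n_expressed cannot exceed n_genes")
        if self.n_network_families > self.n_families:
            raise MalformedInputError("covered families cannot exceed total families")
        if self.n_network < self.n_network_families:
            raise MalformedInputError("n_network must cover n_network_families")
        initial = self.n_network + (self.n_families - self.n_network_families) + self.n_curated
        if self.n_lacking_domain + self.n_synthesis_failed > initial:
            raise MalformedInputError("more removals than selected genes")


@dataclass(frozen=True)
class KinomeSim:
    """Simulated kinome tables plus the planted ground-truth id sets."""

    scenario: KinomeScenario
    expression: pd.DataFrame  # locus_id + one column per library
    families: pd.DataFrame  # locus_id, family, group
    network: pd.DataFrame  # gene_a, gene_b, weight
    flags: pd.DataFrame  # locus_id, has_full_domain
    seed_ids: tuple[str, ...]  # trait-associated genes (network seeds)
    curated_ids: tuple[str, ...]
    failed_ids: tuple[str, ...]
    expressed_ids: tuple[str, ...]  # planted >= threshold genes
    network_ids: tuple[str, ...]  # planted prioritisation outcome

    def genes(self):
        """Materialise :class:`~kinscreen.selection.KinaseGene` records."""
        from .selection import KinaseGene

        lib_cols = [c for c in self.expression.columns if c != "locus_id"]
        fam = self.families.set_index("locus_id")
        flg = self.flags.set_index("locus_id")["has_full_domain"]
        curated = set(self.curated_ids)
        out = []
        for row in self.expression.itertuples(index=False):
            locus = row.locus_id
            out.append(
                KinaseGene(
                    locus_id=locus,
                    family=fam.at[locus, "family"],
                    group=fam.at[locus, "group"],
                    expression=np.array([getattr(row, c) for c in lib_cols]),
                    has_full_domain=bool(flg[locus]),
                    curated=locus in curated,
                )
            )
        return out

    def gene_network(self):
        from .selection import GeneNetwork

        return GeneNetwork.from_edges(
            [(r.gene_a, r.gene_b, r.weight) for r in self.network.itertuples(index=False)]
        )


def simulate_kinome(scenario: KinomeScenario = KinomeScenario()) -> KinomeSim:
    """Generate kinome annotation tables with planted selection ground truth.

    Planted structure: exactly ``n_expressed`` genes have a library maximum at
    or above the 2.0 expression threshold (every family keeps at least two);
    ``n_network`` of them, spread over the ``n_network_families`` families
    with the most expressed genes, carry trait-annotation seed scores and are
    wired into their own network component, so score propagation ranks
    exactly those genes above everything else.  Domain flags and synthesis
    failures are planted on the resulting initial panel at the requested
    counts.
    """
    s = scenario
    groups = ("AGC", "CAMK", "CK1", "CMGC", "STE", "TKL")
    gene_ids = [f"OsK{g:05d}" for g in range(s.n_genes)]
    family_ids = [f"fam{i:02d}" for i in range(s.n_families)]

    rng = substream(s.seed, 10)
    # Non-uniform family sizes: Dirichlet proportions with a floor of 2.
    props = rng.dirichlet(np.full(s.n_families, 1.5))
    sizes = np.maximum(2, np.floor(props * s.n_genes).astype(int))
    while sizes.sum() > s.n_genes:
        sizes[int(np.argmax(sizes))] -= 1
    sizes[int(np.argmax(sizes))] += s.n_genes - sizes.sum()
    family_of: dict[str, str] = {}
    cursor = 0
    for fam, size in zip(family_ids, sizes):
        for locus in gene_ids[cursor : cursor + size]:
            family_of[locus] = fam
        cursor += size
    perm = rng.permutation(s.n_genes)  # decouple id order from family blocks
    family_of = {gene_ids[i]: family_of[gene_ids[perm[i]]] for i in range(s.n_genes)}
    group_of = {fam: groups[i % len(groups)] for i, fam in enumerate(family_ids)}

    by_family: dict[str, list[str]] = {f: [] for f in family_ids}
    for locus, fam in family_of.items():
        by_family[fam].append(locus)

    # Expressed genes: two per family guaranteed, remainder random.
    rng_expr = substream(s.seed, 11)
    expressed: list[str] = []
    for fam in family_ids:
        pick = rng_expr.choice(by_family[fam], size=2, replace=False)
        expressed.extend(pick.tolist())
    remaining = sorted(set(gene_ids) - set(expressed))
    extra = rng_expr.choice(remaining, size=s.n_expressed - len(expressed), replace=False)
    expressed.extend(extra.tolist())
    expressed_set = set(expressed)

    # Network-prioritised genes live in the families with most expressed genes.
    expr_by_family = {f: [g for g in by_family[f] if g in expressed_set] for f in family_ids}
    ranked_families = sorted(
        family_ids, key=lambda f: (-len(expr_by_family[f]), f)
    )[: s.n_network_families]
    rng_net = substream(s.seed, 12)
    network_ids: list[str] = []
    for fam in ranked_families:  # one per covered family first
        network_ids.append(str(rng_net.choice(expr_by_family[fam])))
    pool = sorted(
        g for f in ranked_families for g in expr_by_family[f] if g not in set(network_ids)
    )
    more = rng_net.choice(pool, size=s.n_network - len(network_ids), replace=False)
    network_ids.extend(more.tolist())
    network_set = set(network_ids)

    # Expression matrix: expressed genes get a guaranteed >= 2.0 library value,
    # everything else stays strictly below threshold.
    rng_mat = substream(s.seed, 13)
    values = np.where(
        rng_mat.random((s.n_genes, s.n_libraries)) < 0.35,
        0.0,
        np.round(rng_mat.lognormal(mean=-0.5, sigma=0.8, size=(s.n_genes, s.n_libraries)), 3),
    )
    values = np.minimum(values, 1.95)  # below-threshold baseline for every gene
    idx_of = {g: i for i, g in enumerate(gene_ids)}
    for locus in expressed:
        lib = rng_mat.integers(s.n_libraries)
        values[idx_of[locus], lib] = round(float(rng_mat.uniform(2.0, 40.0)), 3)
    lib_cols = [f"L{j + 1:02d}" for j in range(s.n_libraries)]
    expression = pd.DataFrame(values, columns=lib_cols)
    expression.insert(0, "locus_id", gene_ids)

    # Weighted network: one component among the prioritised genes, background
    # edges among the rest, no cross edges (keeps the planted ranking exact).
    rng_edges = substream(s.seed, 14)
    edges: list[tuple[str, str, float]] = []
    net_sorted = sorted(network_set)
    for i, a in enumerate(net_sorted):  # ring + random chords => connected-ish
        b = net_sorted[(i + 1) % len(net_sorted)]
        edges.append((a, b, round(float(rng_edges.uniform(0.3, 1.0)), 3)))
    n_chords = 3 * len(net_sorted)
    for _ in range(n_chords):
        a, b = rng_edges.choice(net_sorted, size=2, replace=False)
        edges.append((str(a), str(b), round(float(rng_edges.uniform(0.3, 1.0)), 3)))
    others = sorted(set(gene_ids) - network_set)
    for _ in range(2 * len(others)):
        a, b = rng_edges.choice(others, size=2, replace=False)
        edges.append((str(a), str(b), round(float(rng_edges.uniform(0.1, 1.0)), 3)))
    edges = [e for e in edges if e[0] != e[1]]
    network = pd.DataFrame(edges, columns=["gene_a", "gene_b", "weight"]).drop_duplicates(
        subset=["gene_a", "gene_b"]
    )

    # Deterministically recompute the family-coverage additions the selection
    # stage will make, so curated genes and removal flags can be planted on
    # the exact initial panel.
    uncovered = [f for f in family_ids if f not in {family_of[g] for g in network_ids}]
    agg_expr = {g: float(values[idx_of[g]].max()) for g in expressed}
    coverage_ids = [
        min(expr_by_family[f], key=lambda g: (-agg_expr[g], g)) for f in uncovered
    ]

    rng_plan = substream(s.seed, 15)
    curated_pool = sorted(
        g
        for f in ranked_families
        for g in expr_by_family[f]
        if g not in network_set and g not in set(coverage_ids)
    )
    curated_ids = [str(g) for g in rng_plan.choice(curated_pool, size=s.n_curated, replace=False)]

    initial_panel = sorted(set(network_ids) | set(coverage_ids) | set(curated_ids))
    lacking = {
        str(g) for g in rng_plan.choice(initial_panel, size=s.n_lacking_domain, replace=False)
    }
    survivors = [g for g in initial_panel if g not in lacking]
    failed_ids = [
        str(g) for g in rng_plan.choice(survivors, size=s.n_synthesis_failed, replace=False)
    ]

    has_domain = {g: bool(rng_plan.random() < 0.9) for g in gene_ids}
    for g in initial_panel:
        has_domain[g] = True
    for g in lacking:
        has_domain[g] = False

    families = pd.DataFrame(
        {
            "locus_id": gene_ids,
            "family": [family_of[g] for g in gene_ids],
            "group": [group_of[family_of[g]] for g in gene_ids],
        }
    )
    flags = pd.DataFrame(
        {"locus_id": gene_ids, "has_full_domain": [has_domain[g] for g in gene_ids]}
    )
    return KinomeSim(
        scenario=s,
        expression=expression,
        families=families,
        network=network,
        flags=flags,
        seed_ids=tuple(sorted(network_set)),
        curated_ids=tuple(sorted(curated_ids)),
        failed_ids=tuple(sorted(failed_ids)),
        expressed_ids=tuple(sorted(expressed_set)),
        network_ids=tuple(sorted(network_set)),
    )
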