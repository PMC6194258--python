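"""Synthetic gut-microbiota experiments with known ground truth.

The generator emulates the study design this package analyses: 12 gut
samples (3 dietary yeast concentrations x 4 replicate populations) plus one
mock (negative-control) sample. Sequencing read pools are dominated by the
intracellular symbiont *Wolbachia*; the microbiota share of reads grows
with the diet's yeast content. Microbiota composition is
Dirichlet-multinomial around a shared uneven base community, with evenness
(the Dirichlet concentration) decreasing along the yeast gradient so that
alpha diversity declines as abundance rises. Reagent-level contaminant OTUs
are present at a constant absolute load in every sample including the mock,
and a few abundant genuine OTUs leak into the mock at trace level. qPCR Ct
values are derived from the same true quantities through the
efficiency-corrected delta-Ct model, plus Gaussian cycle noise.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import CountMatrix

WOLBACHIA_LINEAGE = ("Bacteria;Proteobacteria;Alphaproteobacteria;"
                     "Rickettsiales;Anaplasmataceae;Wolbachia")
ACETO_LINEAGE = ("Bacteria;Proteobacteria;Alphaproteobacteria;"
                 "Rhodospirillales;Acetobacteraceae;Acetobacter")
FIRMICUTES_LINEAGE = ("Bacteria;Firmicutes;Bacilli;Lactobacillales;"
                      "Lactobacillaceae;Lactobacillus")
# typical reagent/handling contaminants, deliberately outside the two
# qPCR target taxa
CONTAMINANT_LINEAGES = (
    "Bacteria;Actinobacteria;Actinomycetia;Propionibacteriales;"
    "Propionibacteriaceae;Cutibacterium",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Pseudomonadales;"
    "Pseudomonadaceae;Pseudomonas",
)


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic experiment.

    ``ratio_by_diet`` anchors the expected microbiota:*Wolbachia* read
    ratio per diet (0.003 / 0.03 / 1.1 across the 4/10/27% yeast diets);
    the implied true log-linear abundance slope is the least-squares slope
    of log10(ratio) on yeast % through those anchors, ~0.107 decades per
    percentage point (about 2.5 orders of magnitude from 4% to 27%).
    ``dirichlet_by_diet`` sets community evenness per diet; smaller values
    give spikier communities, producing the diversity decline along the
    yeast gradient.
    """

    yeast_pct: tuple[float, ...] = (4.0, 10.0, 27.0)
    replicates_per_diet: int = 4
    n_otus: int = 66
    n_contaminants: int = 17
    ratio_by_diet: tuple[float, ...] = (0.003, 0.03, 1.1)
    log10_ratio_sd: float = 0.3
    dirichlet_by_diet: tuple[float, ...] = (50.0, 10.0, 2.0)
    base_decay: float = 0.94
    reads_per_sample: int = 600_000
    mock_reads: int = 20_000
    wolbachia_quantity: float = 1000.0
    contaminant_quantity: float = 0.5
    n_mock_leak: int = 9
    mock_leak_fraction: float = 1e-3
    ct_intercept: float = 35.0
    ct_noise_sd: float = 0.15
    technical_replicates: int = 2
    eff_universal: float = 1.03
    eff_firmicutes: float = 1.00
    eff_acetobacteraceae: float = 1.03
    eff_rp49: float = 1.00
    host_quantity: float = 1.0
    mock_sample_id: str = "MOCK"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.ratio_by_diet) != len(self.yeast_pct):
            raise ValueError("ratio_by_diet must match yeast_pct")
        if len(self.dirichlet_by_diet) != len(self.yeast_pct):
            raise ValueError("dirichlet_by_diet must match yeast_pct")
        if any(t <= 0 for t in self.dirichlet_by_diet):
            raise ValueError("Dirichlet concentrations must be positive")
        if any(r <= 0 for r in self.ratio_by_diet):
            raise ValueError("ratio anchors must be positive")
        if not 0 < self.base_decay <= 1:
            raise ValueError("base_decay must lie in (0, 1]")
        if not 0 <= self.mock_leak_fraction <= 1:
            raise ValueError("mock_leak_fraction must lie in [0, 1]")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")
        if self.n_mock_leak > self.n_otus:
            raise ValueError("n_mock_leak cannot exceed n_otus")
        if (self.mock_reads > 0 and self.n_contaminants == 0
                and (self.n_mock_leak == 0 or self.mock_leak_fraction == 0)):
            raise ValueError("mock depth > 0 but nothing is seeded into the "
                             "mock: infeasible config")

    @property
    def true_slope(self) -> float:
        """OLS slope of log10(ratio anchors) on yeast %."""
        x = np.asarray(self.yeast_pct, dtype=float)
        y = np.log10(np.asarray(self.ratio_by_diet, dtype=float))
        xc = x - x.mean()
        return float((xc * (y - y.mean())).sum() / (xc ** 2).sum())

    def null(self) -> "SimulationConfig":
        """Diet-independent variant: equal ratio anchors and evenness."""
        k = len(self.yeast_pct)
        mid_r = float(np.exp(np.mean(np.log(self.ratio_by_diet))))
        mid_t = float(np.exp(np.mean(np.log(self.dirichlet_by_diet))))
        return replace(self, ratio_by_diet=(mid_r,) * k,
                       dirichlet_by_diet=(mid_t,) * k)


@dataclass
class GroundTruth:
    """Recovery targets of one simulated experiment."""

    relative_abundances: pd.DataFrame  # genuine OTUs x gut samples
    absolute_abundance: pd.Series  # microbiota quantity per gut sample
    ratio: pd.Series  # true microbiota:Wolbachia quantity ratio
    shannon: pd.Series  # of the true relative abundances, nats
    contaminant_otus: list[str]
    slope: float


@dataclass
class SimulatedExperiment:
    counts: CountMatrix
    metadata: pd.DataFrame
    tree: TreeNode
    taxonomy: pd.Series
    qpcr: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


def simulate_tree(n_otus: int, seed: int, labels=None,
                  branch_length_mean: float = 0.1) -> TreeNode:
    """Random rooted binary tree by sequential random coalescence.

    Branch lengths are i.i.d. exponential; the root branch length is 0.
    Deterministic given (n_otus, seed).
    """
    if n_otus < 2:
        raise ValueError("a tree needs at least 2 leaves")
    if labels is None:
        labels = [f"OTU_{i + 1:04d}" for i in range(n_otus)]
    if len(labels) != n_otus:
        raise ValueError("labels must have length n_otus")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=str(lbl),
                      length=float(rng.exponential(branch_length_mean)))
             for lbl in labels]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = TreeNode(
            children=[a, b],
            length=float(rng.exponential(branch_length_mean)))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


def _ct(quantity: float, eff: float, intercept: float) -> float:
    return intercept - np.log(quantity) / np.log(1.0 + eff)


def simulate_experiment(cfg: SimulationConfig) -> SimulatedExperiment:
    """Draw one complete synthetic experiment from the generative model."""
    rng = np.random.default_rng(cfg.seed)

    genuine = [f"OTU_{i + 1:04d}" for i in range(cfg.n_otus)]
    contaminants = [f"OTU_C{i + 1:02d}" for i in range(cfg.n_contaminants)]
    wolbachia_id = "OTU_WOLB"
    all_otus = genuine + contaminants + [wolbachia_id]

    lineages = {}
    for i, otu in enumerate(genuine):
        lineages[otu] = ACETO_LINEAGE if i % 2 == 0 else FIRMICUTES_LINEAGE
    for i, otu in enumerate(contaminants):
        lineages[otu] = CONTAMINANT_LINEAGES[i % len(CONTAMINANT_LINEAGES)]
    lineages[wolbachia_id] = WOLBACHIA_LINEAGE
    taxonomy = pd.Series(lineages).loc[all_otus]

    tree = simulate_tree(len(all_otus), seed=int(rng.integers(2 ** 31)),
                         labels=all_otus)

    # shared uneven base community (geometric ranked abundances)
    g = cfg.base_decay ** np.arange(cfg.n_otus)
    g = g / g.sum()
    aceto_mask = np.array([i % 2 == 0 for i in range(cfg.n_otus)])

    # constant absolute reagent-contaminant load, shared by every sample
    c_load = cfg.contaminant_quantity * rng.lognormal(
        0.0, 0.25, size=cfg.n_contaminants)

    samples, diets, pops = [], [], []
    for d, yeast in enumerate(cfg.yeast_pct):
        for r in range(cfg.replicates_per_diet):
            samples.append(f"Y{int(round(yeast)):02d}_P{r + 1}")
            diets.append(float(yeast))
            pops.append(str(r + 1))
    metadata = pd.DataFrame(
        {"diet_yeast_pct": diets, "population": pops},
        index=pd.Index(samples, name="sample"))

    n_all = len(all_otus)
    counts = np.zeros((n_all, len(samples) + 1), dtype=np.int64)
    p_true = np.zeros((cfg.n_otus, len(samples)))
    ratios = np.zeros(len(samples))
    for j, sample in enumerate(samples):
        d = j // cfg.replicates_per_diet
        eps = rng.normal(0.0, cfg.log10_ratio_sd)
        ratio = cfg.ratio_by_diet[d] * 10.0 ** eps
        a_total = cfg.wolbachia_quantity * ratio
        p = rng.dirichlet(cfg.dirichlet_by_diet[d] * g)
        p_true[:, j] = p
        ratios[j] = ratio
        q = np.concatenate([a_total * p, c_load, [cfg.wolbachia_quantity]])
        counts[:, j] = rng.multinomial(cfg.reads_per_sample, q / q.sum())

    # mock: contaminants at their reagent load plus trace leaks of the most
    # abundant genuine OTUs picked up during handling
    a_mean = cfg.wolbachia_quantity * float(np.mean(ratios))
    leak = np.zeros(cfg.n_otus)
    leak[:cfg.n_mock_leak] = cfg.mock_leak_fraction * a_mean \
        * g[:cfg.n_mock_leak]
    q_mock = np.concatenate([leak, c_load, [0.0]])
    if cfg.mock_reads > 0:
        counts[:, -1] = rng.multinomial(cfg.mock_reads,
                                        q_mock / q_mock.sum())

    all_samples = samples + [cfg.mock_sample_id]
    cm = CountMatrix(
        pd.DataFrame(counts, index=all_otus, columns=all_samples),
        mock_sample=cfg.mock_sample_id)

    # qPCR: Ct from true quantities via the efficiency-corrected model
    a_by_sample = cfg.wolbachia_quantity * ratios
    q_univ = a_by_sample + c_load.sum() + cfg.wolbachia_quantity
    q_univ_mock = q_mock.sum()
    rows = []

    def add(sample, target, quantity, eff):
        base = _ct(quantity, eff, cfg.ct_intercept)
        for _ in range(cfg.technical_replicates):
            rows.append({"sample": sample, "target": target,
                         "ct": base + rng.normal(0.0, cfg.ct_noise_sd),
                         "efficiency": eff})

    for j, sample in enumerate(samples):
        q_aceto = a_by_sample[j] * float(p_true[aceto_mask, j].sum())
        q_firm = a_by_sample[j] * float(p_true[~aceto_mask, j].sum())
        add(sample, "universal_16S", q_univ[j], cfg.eff_universal)
        add(sample, "rp49", cfg.host_quantity, cfg.eff_rp49)
        add(sample, "Acetobacteraceae", q_aceto, cfg.eff_acetobacteraceae)
        add(sample, "Firmicutes", q_firm, cfg.eff_firmicutes)
    add(cfg.mock_sample_id, "universal_16S", q_univ_mock, cfg.eff_universal)
    qpcr = pd.DataFrame(rows)

    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(p_true > 0, np.log(np.where(p_true > 0, p_true, 1)),
                        0.0)
    truth = GroundTruth(
        relative_abundances=pd.DataFrame(p_true, index=genuine,
                                         columns=samples),
        absolute_abundance=pd.Series(a_by_sample, index=samples),
        ratio=pd.Series(ratios, index=samples),
        shannon=pd.Series(-(p_true * logs).sum(axis=0), index=samples),
        contaminant_otus=list(contaminants),
        slope=cfg.true_slope)
    return SimulatedExperiment(counts=cm, metadata=metadata, tree=tree,
                               taxonomy=taxonomy, qpcr=qpcr, truth=truth,
                               config=cfg)
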