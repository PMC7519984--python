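"""Synthetic paired miRNA/mRNA study generator with recorded ground truth.

The generator emulates the structure of the heat time-course microarray
design the pipeline targets: five timepoints (0 min control, 10 min, 20 min,
60 min, 2 h), two replicates each, miRNA and mRNA probes measured on log2
scale.  Every stage of the pipeline can be exercised against the recorded
truth: which entities are differentially expressed and with what signed
per-timepoint effects, which (family, gene) pairs are planted as
anti-correlated regulator/target pairs, where target sites sit in the
simulated transcripts and what they should score, and which gene groups form
high-confidence PPI modules.

Value model, entity i in sample s at timepoint t:

    y_is = baseline_i + sign_i * effect_size * profile(t) * [i is DE] + eps,
    eps ~ Normal(0, noise_sd^2),  baseline_i ~ Uniform(6, 14) log2 units.

The default effect profile is a ramp that reaches its maximum at the late
timepoints, mirroring a response that builds over the time course; a
constant step profile is also available.  Detection flags are P unless a
cell's intensity falls below the dropout threshold, in which case the cell
is flagged A with probability ``flag_dropout`` (low-intensity dropout, the
failure mode present-call filtering exists for).

All randomness flows from the single mandatory seed; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from heatmir.containers import DEFAULT_TIMEPOINTS, ExpressionMatrix
from heatmir.errors import ConfigError
from heatmir.targets import reverse_complement

RAMP_PROFILE = (0.5, 0.75, 1.0, 1.0)
STEP_PROFILE = (1.0, 1.0, 1.0, 1.0)

_MISMATCH_CHOICES = {  # target bases that mismatch (no match, no G:U wobble)
    "A": "ACG", "C": "ACU", "G": "AG", "U": "CU", "N": "ACGU",
}


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator."""

    n_mirnas: int = 200
    n_genes: int = 1800
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 2
    frac_de_mirnas: float = 0.2
    frac_de_genes: float = 0.15
    effect_size: float = 2.0
    noise_sd: float = 0.2
    frac_anticorrelated_pairs: float = 0.8
    flag_dropout: float = 0.3
    dropout_threshold: float = 6.5  # detection floor = top of background range
    frac_background: float = 0.1
    background_range: tuple[float, float] = (4.0, 6.5)
    de_baseline_range: tuple[float, float] | None = None
    effect_profile: str = "ramp"
    baseline_range: tuple[float, float] = (6.0, 14.0)
    mirna_length: int = 21
    transcript_length: int = 500
    n_ppi_modules: int = 2
    ppi_module_size: int = 3
    n_ppi_background: int = 200
    seed: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is mandatory for reproducibility")
        for name in ("frac_de_mirnas", "frac_de_genes",
                     "frac_anticorrelated_pairs", "flag_dropout",
                     "frac_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.effect_profile not in ("ramp", "step"):
            raise ConfigError(f"unknown effect_profile {self.effect_profile!r}")
        if self.n_mirnas < 1 or self.n_genes < 1 or self.n_replicates < 1:
            raise ConfigError("n_mirnas, n_genes, n_replicates must be positive")
        if self.de_baseline_range is None:
            # planted effects keep headroom on both sides of the detectable
            # range: repression must not fall below the detection floor and
            # induction must not run past the top of the dynamic range,
            # otherwise the planted truth is not recoverable by any method
            self.de_baseline_range = (
                self.dropout_threshold + self.effect_size,
                self.baseline_range[1] - self.effect_size,
            )
        if self.de_baseline_range[0] >= self.de_baseline_range[1]:
            raise ConfigError(
                "effect_size leaves no measurable baseline range for DE entities"
            )

    @property
    def profile(self) -> tuple[float, ...]:
        base = RAMP_PROFILE if self.effect_profile == "ramp" else STEP_PROFILE
        n_treat = len(self.timepoints) - 1
        if n_treat == len(base):
            return base
        # stretch/shrink to the configured number of treatment timepoints
        xs = np.linspace(0, 1, n_treat) if n_treat > 1 else np.array([1.0])
        return tuple(np.interp(xs, np.linspace(0, 1, len(base)), base))


@dataclass
class GroundTruth:
    """Everything planted by the generator, for recovery checks."""

    family_of: dict[str, str]
    mirna_effects: dict[str, dict[str, float]]  # id -> timepoint -> signed log2
    gene_effects: dict[str, dict[str, float]]
    de_mirnas: set[str] = field(default_factory=set)
    de_genes: set[str] = field(default_factory=set)
    background_probes: set[str] = field(default_factory=set)
    pairs: list[tuple[str, str]] = field(default_factory=list)  # (family, gene)
    sites: pd.DataFrame | None = None
    ppi_modules: list[list[str]] = field(default_factory=list)

    @property
    def de_families(self) -> set[str]:
        return {self.family_of[m] for m in self.de_mirnas}


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _mirna_ids(cfg: SimulationConfig, rng: np.random.Generator):
    """Mature ids grouped into families of 1-3 members (osa-miR1001a style)."""
    family_of: dict[str, str] = {}
    ids: list[str] = []
    fam_idx = 0
    while len(ids) < cfg.n_mirnas:
        fam = f"osa-miR{1001 + fam_idx}"
        fam_idx += 1
        n_members = min(int(rng.integers(1, 4)), cfg.n_mirnas - len(ids))
        for j in range(n_members):
            mid = f"{fam}{'abc'[j]}" if n_members > 1 else fam
            ids.append(mid)
            family_of[mid] = fam
    return ids, family_of


def _gene_ids(cfg: SimulationConfig) -> list[str]:
    return [
        f"LOC_Os{(i % 12) + 1:02d}g{10000 + i:05d}" for i in range(cfg.n_genes)
    ]


def simulate_expression(cfg: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the joint miRNA+mRNA expression matrix with flags and truth."""
    rng = np.random.default_rng(cfg.seed)
    mirna_ids, family_of = _mirna_ids(cfg, rng)
    gene_ids = _gene_ids(cfg)
    families = sorted(set(family_of.values()))
    treat_tps = list(cfg.timepoints[1:])
    profile = np.asarray(cfg.profile)

    # DE families (members move together) until ~frac_de_mirnas of miRNAs
    members_by_family = {
        f: [m for m in mirna_ids if family_of[m] == f] for f in families
    }
    shuffled = list(families)
    rng.shuffle(shuffled)
    target_n = round(cfg.frac_de_mirnas * cfg.n_mirnas)
    de_families: list[str] = []
    de_mirnas: set[str] = set()
    for fam in shuffled:
        if len(de_mirnas) >= target_n:
            break
        de_families.append(fam)
        de_mirnas.update(members_by_family[fam])
    family_sign = {f: int(rng.choice([-1, 1])) for f in de_families}

    # DE genes: planted anti-correlated partners first, then independent ones
    n_pairs = round(cfg.frac_anticorrelated_pairs * len(de_families))
    n_de_genes = max(round(cfg.frac_de_genes * cfg.n_genes), n_pairs)
    de_gene_list = [str(g) for g in rng.choice(gene_ids, size=n_de_genes, replace=False)]
    pair_families = sorted(de_families)[:n_pairs]
    pairs = [(fam, de_gene_list[i]) for i, fam in enumerate(pair_families)]
    gene_sign: dict[str, int] = {}
    for i, gene in enumerate(de_gene_list):
        if i < n_pairs:
            gene_sign[gene] = -family_sign[pair_families[i]]
        else:
            gene_sign[gene] = int(rng.choice([-1, 1]))

    # assemble values
    probe_ids = mirna_ids + gene_ids
    n_probes = len(probe_ids)
    sample_ids, tp_of_sample = [], []
    for tp in cfg.timepoints:
        for rep in range(1, cfg.n_replicates + 1):
            sample_ids.append(f"{tp}_r{rep}")
            tp_of_sample.append(tp)
    baseline = rng.uniform(*cfg.baseline_range, size=n_probes)

    # background (not-detected) probes: low intensity in every sample, never
    # DE -- they populate the low tail of each sample's distribution the way
    # absent-call probes do on a real array, and give the present-call
    # filter its job
    expressed_de = set(de_mirnas) | set(de_gene_list)
    non_de_mirnas = [m for m in mirna_ids if m not in expressed_de]
    non_de_genes = [g for g in gene_ids if g not in expressed_de]
    background: list[str] = []
    for pool, n_total in ((non_de_mirnas, cfg.n_mirnas), (non_de_genes, cfg.n_genes)):
        n_bg = min(round(cfg.frac_background * n_total), len(pool))
        background.extend(str(p) for p in rng.choice(pool, size=n_bg, replace=False))
    probe_index_tmp = {p: i for i, p in enumerate(probe_ids)}
    for p in background:
        baseline[probe_index_tmp[p]] = rng.uniform(*cfg.background_range)

    # planted DE entities sit in the mid dynamic range: an induction of an
    # already-saturated probe (or repression into background) is not
    # measurable on any array, so effects planted there would not be
    # recoverable ground truth
    for p in sorted(expressed_de):
        baseline[probe_index_tmp[p]] = rng.uniform(*cfg.de_baseline_range)

    effect = np.zeros((n_probes, len(sample_ids)))
    mirna_effects: dict[str, dict[str, float]] = {}
    gene_effects: dict[str, dict[str, float]] = {}
    probe_index = {p: i for i, p in enumerate(probe_ids)}
    tp_effect_index = {tp: k for k, tp in enumerate(treat_tps)}

    def plant(entity: str, sign: int, store: dict) -> None:
        per_tp = {
            tp: sign * cfg.effect_size * profile[tp_effect_index[tp]]
            for tp in treat_tps
        }
        store[entity] = per_tp
        i = probe_index[entity]
        for j, tp in enumerate(tp_of_sample):
            if tp in per_tp:
                effect[i, j] = per_tp[tp]

    for fam in de_families:
        for m in members_by_family[fam]:
            plant(m, family_sign[fam], mirna_effects)
    for gene in de_gene_list:
        plant(gene, gene_sign[gene], gene_effects)

    noise = rng.normal(0.0, cfg.noise_sd, size=effect.shape)
    values = baseline[:, None] + effect + noise

    low = values < cfg.dropout_threshold
    dropout = rng.random(size=values.shape) < cfg.flag_dropout
    flags = np.where(low & dropout, "A", "P")

    samples = pd.DataFrame(
        {
            "timepoint": pd.Categorical(
                tp_of_sample, categories=list(cfg.timepoints), ordered=True
            ),
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        samples=samples,
        flags=pd.DataFrame(flags, index=probe_ids, columns=sample_ids),
    )
    truth = GroundTruth(
        family_of=family_of,
        mirna_effects=mirna_effects,
        gene_effects=gene_effects,
        de_mirnas=de_mirnas,
        de_genes=set(de_gene_list),
        background_probes=set(background),
        pairs=pairs,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def _mismatch_base(rng: np.random.Generator, mirna_base: str) -> str:
    return str(rng.choice(list(_MISMATCH_CHOICES[mirna_base])))


def _plant_site(rng, mirna_seq: str, kind: str) -> tuple[str, float]:
    """Build a target-site sequence of the requested expectation class.

    ``perfect`` scores 0; ``defect`` carries one non-seed mismatch
    (expectation 1.0); ``decoy`` carries two seed mismatches (expectation
    4.0, safely past the 3.0 cutoff).  Returns (site 5'->3', expectation).
    """
    L = len(mirna_seq)
    site = list(reverse_complement(mirna_seq))  # site[L-1-(p-1)] faces miRNA pos p
    if kind == "perfect":
        return "".join(site), 0.0
    if kind == "defect":
        pos = int(rng.integers(14, L + 1))  # non-seed miRNA position
        site[L - pos] = _mismatch_base(rng, mirna_seq[pos - 1])
        return "".join(site), 1.0
    if kind == "decoy":
        for pos in (3, 7):  # two seed mismatches: 2 * (1.0 * 2)
            site[L - pos] = _mismatch_base(rng, mirna_seq[pos - 1])
        return "".join(site), 4.0
    raise ConfigError(f"unknown site kind {kind!r}")


def simulate_sequences(
    cfg: SimulationConfig,
    truth: GroundTruth,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Random miRNA and transcript sequences with planted target sites.

    Each planted (family, gene) pair receives a real site (alternating
    perfect and single-defect classes) in the gene's transcript for the
    family's first member; an equal number of non-paired DE genes receive
    decoy near-sites that must score past the cutoff.  The returned site
    table records the intended expectation of every planted site.
    Updates ``truth.sites`` in place and also returns the table.
    """
    rng = np.random.default_rng((cfg.seed, 1))
    mirna_ids = sorted(truth.family_of)
    mirnas = {m: _random_seq(rng, cfg.mirna_length) for m in mirna_ids}
    genes = sorted(truth.gene_effects) if truth.gene_effects else []
    all_genes = sorted(set(genes) | {g for _, g in truth.pairs})
    transcripts = {
        g: _random_seq(rng, cfg.transcript_length) for g in all_genes
    }

    first_member = {}
    for mid in mirna_ids:
        first_member.setdefault(truth.family_of[mid], mid)

    records = []

    def embed(gene: str, mirna_id: str, kind: str) -> None:
        seq = transcripts[gene]
        site, expectation = _plant_site(rng, mirnas[mirna_id], kind)
        start = int(rng.integers(0, len(seq) - len(site) + 1))
        transcripts[gene] = seq[:start] + site + seq[start + len(site):]
        records.append({
            "mirna_id": mirna_id,
            "transcript_id": gene,
            "start": start + 1,
            "expectation": expectation,
            "kind": kind,
        })

    for i, (fam, gene) in enumerate(truth.pairs):
        embed(gene, first_member[fam], "perfect" if i % 2 == 0 else "defect")

    paired_genes = {g for _, g in truth.pairs}
    decoy_candidates = [g for g in genes if g not in paired_genes]
    de_family_members = sorted(
        m for m in mirna_ids if truth.family_of[m] in truth.de_families
    ) or mirna_ids
    for i, gene in enumerate(decoy_candidates[: len(truth.pairs)]):
        embed(gene, de_family_members[i % len(de_family_members)], "decoy")

    sites = pd.DataFrame(
        records,
        columns=["mirna_id", "transcript_id", "start", "expectation", "kind"],
    )
    truth.sites = sites
    return mirnas, transcripts, sites


# ---------------------------------------------------------------------------
# PPI
# ---------------------------------------------------------------------------

def simulate_ppi(
    cfg: SimulationConfig,
    truth: GroundTruth,
) -> pd.DataFrame:
    """PPI edge table with planted high-confidence modules.

    Planted modules group genes drawn from *different* planted pairs, so the
    module finder must connect their families through the protein layer:
    within-module gene pairs score Uniform(0.75, 0.99) (always past the 0.7
    cutoff), background pairs Uniform(0.0, 0.65) (never past it).  Updates
    ``truth.ppi_modules`` and returns the edge table.
    """
    rng = np.random.default_rng((cfg.seed, 2))
    pair_genes = [g for _, g in truth.pairs]
    modules: list[list[str]] = []
    idx = 0
    for _ in range(cfg.n_ppi_modules):
        group = pair_genes[idx: idx + cfg.ppi_module_size]
        idx += cfg.ppi_module_size
        if len(group) >= 2:
            modules.append(sorted(group))
    if cfg.n_ppi_modules > 0 and len(modules) < cfg.n_ppi_modules:
        raise ConfigError(
            "not enough planted pair genes to build the requested PPI modules"
        )
    truth.ppi_modules = modules

    rows = []
    in_module = set()
    for module in modules:
        in_module.update(module)
        for i, a in enumerate(module):
            for b in module[i + 1:]:
                rows.append((a, b, float(rng.uniform(0.75, 0.99))))
    background_pool = sorted(set(truth.gene_effects) - in_module)
    n_bg = min(cfg.n_ppi_background,
               len(background_pool) * (len(background_pool) - 1) // 2)
    seen = {(a, b) for a, b, _ in rows}
    target_total = len(seen) + n_bg
    while len(seen) < target_total and len(background_pool) >= 2:
        a, b = rng.choice(background_pool, size=2, replace=False)
        a, b = sorted((str(a), str(b)))
        if (a, b) in seen:
            continue
        seen.add((a, b))
        rows.append((a, b, float(rng.uniform(0.0, 0.65))))
    df = pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"])
    return df.sort_values(["protein_a", "protein_b"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    matrix: ExpressionMatrix
    truth: GroundTruth
    mirnas: dict[str, str]
    transcripts: dict[str, str]
    ppi: pd.DataFrame


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Run all three generators off one seed and bundle the results."""
    matrix, truth = simulate_expression(cfg)
    mirnas, transcripts, _ = simulate_sequences(cfg, truth)
    ppi = simulate_ppi(cfg, truth)
    return SimulatedStudy(matrix=matrix, truth=truth, mirnas=mirnas,
                          transcripts=transcripts, ppi=ppi)
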