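"""End-to-end orchestration: config validation, stage wiring, artifacts.

``run_all`` executes preprocess -> differential expression -> family
aggregation -> target prediction -> anti-correlation pairing -> network
assembly -> annotation, and writes every result table plus a deterministic
run manifest.  Three input modes exist:

* ``simulate`` -- generate a synthetic study from the seed in the config;
* ``files``    -- read expression matrix, flags, sample sheet, FASTAs, PPI
  and annotation tables from the configured paths;
* ``fixture``  -- bypass expression processing and drive pairing, network
  and annotation directly from the packaged curated pair table (useful
  where only the published summary tables, not the raw arrays, are at
  hand).

Probes whose ids follow the miRNA naming convention (<prefix>-miR<number>…)
are treated as miRNA probes; all others as gene probes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from heatmir import __version__, annotate, datasets, diffexpr, io
from heatmir import network as net
from heatmir import pairing, preprocess, targets
from heatmir.containers import ExpressionMatrix, FamilyProfile
from heatmir.errors import ConfigError
from heatmir.simulate import SimulationConfig, simulate_study

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "mode": "simulate",
    "seed": 1,
    "simulate": {
        "n_mirnas": 200,
        "n_genes": 1800,
        "n_replicates": 2,
        "frac_de_mirnas": 0.2,
        "frac_de_genes": 0.15,
        "effect_size": 2.0,
        "noise_sd": 0.2,
        "frac_anticorrelated_pairs": 0.8,
        "frac_background": 0.1,
        "flag_dropout": 0.3,
        "effect_profile": "ramp",
        "n_ppi_modules": 2,
        "ppi_module_size": 3,
        "n_ppi_background": 200,
    },
    "inputs": {
        "matrix": None,
        "flags": None,
        "sample_sheet": None,
        "mirna_fasta": None,
        "transcript_fasta": None,
        "ppi": None,
        "ppi_score_scale": "unit",
        "goslim": None,
        "ogro": None,
    },
    "preprocess": {"min_present": None, "log_floor": 1.0, "input_scale": "log2"},
    "de": {
        "method": "moderated_t",
        "lfc_threshold": 1.0,
        "alpha": 0.05,
        "control_timepoint": None,
    },
    "targets": {"cutoff": 3.0, "max_gaps": 1},
    "pairing": {"mode": "same_timepoint"},
    "network": {"min_ppi_score": 0.7},
}

ARTIFACTS = [
    "de_mirnas.tsv", "de_genes.tsv", "family_profiles.tsv", "predictions.tsv",
    "hc_pairs.tsv", "timecourse_counts.tsv", "network.graphml", "network.sif",
    "modules.tsv", "degree_report.tsv", "stress_bipartite.graphml",
    "goslim_counts.tsv", "ogro_hits.tsv", "manifest.json",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, default in defaults.items():
        here = f"{path}.{key}" if path else key
        if key in user:
            value = user[key]
            if isinstance(default, dict) and isinstance(value, dict):
                out[key] = _merge(default, value, here)
            else:
                out[key] = value
        else:
            out[key] = default
    unknown = set(user) - set(defaults)
    if unknown:
        bad = sorted(unknown)[0]
        raise ConfigError(
            f"unknown config key {(path + '.' if path else '') + bad!r}"
        )
    return out


def validate_config(config) -> dict:
    """Normalize a config (path, mapping, or None): fill defaults, reject
    unknown keys.  Idempotent."""
    if config is None:
        user: dict = {}
    elif isinstance(config, (str, Path)):
        with open(config) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(config)
    cfg = _merge(DEFAULT_CONFIG, user)
    if cfg["mode"] not in ("simulate", "files", "fixture"):
        raise ConfigError(f"unknown mode {cfg['mode']!r}")
    return cfg


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def is_mirna_probe(probe_id: str) -> bool:
    return diffexpr.MIRNA_ID_RE.match(str(probe_id)) is not None


def split_probes(m: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Partition a joint matrix into miRNA-probe and gene-probe matrices."""
    mirna_ids = [p for p in m.probe_ids if is_mirna_probe(p)]
    gene_ids = [p for p in m.probe_ids if not is_mirna_probe(p)]
    return m.subset_probes(mirna_ids), m.subset_probes(gene_ids)


def _write_tsv(df: pd.DataFrame, path: Path, index=False, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g", **kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, cfg: dict, filenames: list[str]) -> None:
    manifest = {
        "package_version": __version__,
        "seed": cfg["seed"],
        "config": cfg,
        "outputs": {
            name: _sha256(outdir / name)
            for name in sorted(filenames)
            if (outdir / name).exists()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def preprocess_matrix(m: ExpressionMatrix, cfg: dict) -> ExpressionMatrix:
    pcfg = cfg["preprocess"]
    if pcfg["input_scale"] == "raw":
        m = m.with_values(preprocess.log2_transform(m.values, pcfg["log_floor"]))
    elif pcfg["input_scale"] != "log2":
        raise ConfigError(f"unknown input_scale {pcfg['input_scale']!r}")
    if m.flags is not None:
        m = preprocess.filter_by_flags(m, pcfg["min_present"])
    dropped = m.values.index[m.values.isna().any(axis=1)]
    if len(dropped):
        logger.warning("dropping %d probes with missing values", len(dropped))
        m = m.subset_probes([p for p in m.probe_ids if p not in set(dropped)])
    m = preprocess.quantile_normalize(m)
    return preprocess.baseline_to_median(m)


def run_de(m: ExpressionMatrix, cfg: dict) -> pd.DataFrame:
    dcfg = cfg["de"]
    profiles = diffexpr.de_profile(
        m, control=dcfg["control_timepoint"], method=dcfg["method"]
    )
    return diffexpr.call_de(
        profiles, lfc_threshold=dcfg["lfc_threshold"], alpha=dcfg["alpha"]
    )


def run_predictions(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    de_mirna_ids,
    cfg: dict,
) -> pd.DataFrame:
    """Predict targets of the DE miRNAs (member level)."""
    de_seqs = {m: s for m, s in mirnas.items() if m in set(de_mirna_ids)}
    if not de_seqs or not transcripts:
        return pd.DataFrame(
            columns=["mirna_id", "transcript_id", "start", "end",
                     "expectation", "mode", "alignment"]
        )
    return targets.predict_targets(
        de_seqs, transcripts,
        cutoff=cfg["targets"]["cutoff"], max_gaps=cfg["targets"]["max_gaps"],
    )


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def run_all(config, outdir) -> Path:
    """Execute the full pipeline per the config; returns the output dir."""
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg["mode"] == "fixture":
        return run_fixture(outdir, cfg)

    stage = "inputs"
    try:
        if cfg["mode"] == "simulate":
            sim_cfg = SimulationConfig(**cfg["simulate"], seed=cfg["seed"])
            study = simulate_study(sim_cfg)
            matrix = study.matrix
            mirnas, transcripts, ppi = study.mirnas, study.transcripts, study.ppi
            goslim = ogro = None
        else:
            inp = cfg["inputs"]
            for key in ("matrix", "sample_sheet"):
                if not inp[key]:
                    raise ConfigError(f"files mode needs inputs.{key}")
            matrix = io.read_expression_matrix(
                inp["matrix"], inp["sample_sheet"], flag_path=inp["flags"]
            )
            mirnas = io.read_fasta(inp["mirna_fasta"]) if inp["mirna_fasta"] else {}
            transcripts = (
                io.read_fasta(inp["transcript_fasta"])
                if inp["transcript_fasta"] else {}
            )
            ppi = (
                io.read_ppi_edges(inp["ppi"], score_scale=inp["ppi_score_scale"])
                if inp["ppi"] else None
            )
            goslim = io.read_goslim_table(inp["goslim"]) if inp["goslim"] else None
            ogro = io.read_ogro_table(inp["ogro"]) if inp["ogro"] else None

        stage = "preprocess"
        matrix = preprocess_matrix(matrix, cfg)
        mirna_m, gene_m = split_probes(matrix)

        stage = "diffexpr"
        mirna_calls = run_de(mirna_m, cfg)
        gene_calls = run_de(gene_m, cfg)
        _write_tsv(mirna_calls, outdir / "de_mirnas.tsv", index=True,
                   index_label="mirna_id")
        _write_tsv(gene_calls, outdir / "de_genes.tsv", index=True,
                   index_label="gene_id")

        stage = "family_aggregation"
        family_profiles = diffexpr.aggregate_families(mirna_calls)
        _write_tsv(diffexpr.family_profile_table(family_profiles),
                   outdir / "family_profiles.tsv")

        stage = "target_prediction"
        de_mirna_ids = mirna_calls.index[mirna_calls["de"]]
        predictions = run_predictions(mirnas, transcripts, de_mirna_ids, cfg)
        _write_tsv(predictions, outdir / "predictions.tsv")
        fam_targets = targets.family_level_targets(
            predictions, diffexpr.map_to_family
        )

        stage = "pairing"
        cand = pairing.candidate_pairs(fam_targets, family_profiles, gene_calls)
        hc = pairing.high_confidence_pairs(
            cand, family_profiles, gene_calls, mode=cfg["pairing"]["mode"]
        )
        _write_tsv(hc, outdir / "hc_pairs.tsv")
        hc_gene_calls = gene_calls.loc[sorted(set(hc["gene_id"]))] \
            if len(hc) else gene_calls.iloc[0:0]
        counts = pairing.timecourse_counts(
            mirna_calls[mirna_calls["de"]], hc_gene_calls
        )
        _write_tsv(counts, outdir / "timecourse_counts.tsv")

        stage = "network"
        graph = net.build_mirna_ppi_network(
            hc, ppi_edges=ppi, min_ppi_score=cfg["network"]["min_ppi_score"]
        )
        io.write_network(graph, outdir / "network.graphml", "graphml")
        io.write_network(graph, outdir / "network.sif", "sif")
        modules = net.find_coregulatory_modules(graph)
        _write_tsv(net.module_table(modules), outdir / "modules.tsv")
        _write_tsv(net.degree_report(graph), outdir / "degree_report.tsv")
        bipartite = net.build_family_stress_bipartite(family_profiles)
        io.write_network(bipartite, outdir / "stress_bipartite.graphml", "graphml")

        stage = "annotate"
        hc_genes = sorted(set(hc["gene_id"]))
        _write_goslim(hc_genes, goslim, outdir)
        _write_ogro(hc_genes, ogro, outdir)
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_manifest(outdir, cfg, [a for a in ARTIFACTS if a != "manifest.json"])
    return outdir


def _write_goslim(genes, goslim, outdir: Path) -> None:
    if goslim is None:
        goslim = pd.DataFrame(columns=["gene_id", "aspect", "term"])
    tables, unannotated = annotate.goslim_counts(genes, goslim)
    combined = pd.concat(
        [t.assign(aspect=a)[["aspect", "term", "count", "percentage"]]
         for a, t in tables.items()],
        ignore_index=True,
    )
    _write_tsv(combined, outdir / "goslim_counts.tsv")
    (outdir / "goslim_unannotated.txt").write_text(
        "".join(f"{g}\n" for g in unannotated)
    )


def _write_ogro(genes, ogro, outdir: Path) -> None:
    if ogro is None:
        ogro = datasets.load_ogro_table().iloc[0:0]
    hits, n_loci = annotate.ogro_lookup(genes, ogro)
    _write_tsv(hits, outdir / "ogro_hits.tsv")


def run_fixture(outdir, config=None) -> Path:
    """Drive pairing, network and annotation from the packaged curated table.

    The curated table already encodes the high-confidence pairs with overall
    direction labels; per-site regulation modes are not part of it, so all
    regulation edges take the default ``cleavage`` kind.  Writes a summary
    of the headline counts alongside the usual network artifacts.
    """
    cfg = validate_config(config) if not isinstance(config, dict) else config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = datasets.load_hc_pair_table()
    hc = table.rename(
        columns={"family_direction": "family_overall",
                 "gene_direction": "gene_overall"}
    )
    hc["mode"] = "cleavage"
    _write_tsv(hc, outdir / "hc_pairs.tsv")

    graph = net.build_mirna_ppi_network(hc, ppi_edges=None)
    io.write_network(graph, outdir / "network.graphml", "graphml")
    io.write_network(graph, outdir / "network.sif", "sif")
    modules = net.find_coregulatory_modules(graph)
    _write_tsv(net.module_table(modules), outdir / "modules.tsv")
    degrees = net.degree_report(graph)
    _write_tsv(degrees, outdir / "degree_report.tsv")

    family_dirs = hc.drop_duplicates("family").set_index("family")["family_overall"]
    profiles = {
        fam: FamilyProfile(family=fam, members=[], direction_by_timepoint={},
                           overall_direction=d)
        for fam, d in family_dirs.items()
    }
    bipartite = net.build_family_stress_bipartite(profiles)
    io.write_network(bipartite, outdir / "stress_bipartite.graphml", "graphml")

    genes = sorted(set(hc["gene_id"]))
    _write_goslim(genes, datasets.load_goslim_table(), outdir)
    ogro = datasets.load_ogro_table()
    hits, n_loci = annotate.ogro_lookup(genes, ogro)
    _write_tsv(hits, outdir / "ogro_hits.tsv")

    fam_degrees = degrees[degrees["type"] == "family"]
    top = fam_degrees.iloc[0]
    summary = {
        "n_families": int(hc["family"].nunique()),
        "n_hc_target_genes": len(genes),
        "max_family_target_count": int(top["target_count"]),
        "max_target_family": str(top["node"]),
        "n_characterized_loci": int(n_loci),
        "n_modules": len(modules),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_manifest(outdir, cfg, [
        "hc_pairs.tsv", "network.graphml", "network.sif", "modules.tsv",
        "degree_report.tsv", "stress_bipartite.graphml", "goslim_counts.tsv",
        "ogro_hits.tsv", "summary.json",
    ])
    return outdir
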