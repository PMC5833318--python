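"""End-to-end pipeline: simulate -> call -> rates -> spectrum -> context
-> MNM -> Ne, driven by one YAML config with all randomness seeded.

The summary is emitted both as a flat TSV of (field, value) pairs and as
structured text; field names are frozen so downstream tooling can rely
on them.
"""

from __future__ import annotations

import logging
import sys
import time
from pathlib import Path

import yaml

from . import fixture, pileio
from .calling import CallingThresholds, call_all_lines
from .context import bin_density, coding_distribution_test, ns_s_expectation_test, terminus_test
from .mnm import MnmParams, clustered_event_count, detect_mnm, mnm_expected_probability
from .popgen import effective_population_size, silent_site_pi_from_fasta
from .rates import catalog_rates
from .simulate import SimulationConfig, emit_pileups, simulate
from .spectrum import deletion_bias_test, summarize_spectrum

log = logging.getLogger("macall")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                log.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.time() - t0)
            return out

        return wrapped

    return deco


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def run_pipeline(config: dict, outdir) -> dict:
    """Run every stage and return the flat summary mapping.

    ``config`` keys: either ``fixture: true`` (analyze the catalog
    reconstructed from the published study totals) or a ``simulate``
    section with SimulationConfig fields; optional ``thresholds``
    overrides, ``bin_size``, ``windows``, ``alignment`` (FASTA path for
    pi_S / Ne), and ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    summary: dict[str, object] = {}
    seed = int(config.get("seed", 0))
    thresholds = CallingThresholds(**config.get("thresholds", {}))
    windows = config.get("windows", [20, 50, 100])
    bin_size = int(config.get("bin_size", 50_000))

    genome = None
    truth = None
    if config.get("fixture"):
        catalog = _stage("fixture")(fixture.build_catalog)(config.get("totals"))
        genome_size = (config.get("totals") or fixture.STUDY_TOTALS)["genome_size"]
    elif "simulate" in config:
        sim_cfg = SimulationConfig(**{**config["simulate"], "seed": seed})
        simdata = _stage("simulate")(simulate)(sim_cfg)
        genome, truth = simdata.genome, simdata.truth
        genome_size = genome.length
        if config.get("write_pileups", False):
            _stage("emit")(emit_pileups)(simdata, outdir / "sim")
        catalog = _stage("call")(call_all_lines)(
            simdata.counts, simdata.evidence, sim_cfg.generations, thresholds
        )
    elif "pileup_dir" in config:
        catalog = _stage("call")(_call_from_directory)(config, thresholds)
        genome_size = int(config["genome_length"])
    else:
        raise ValueError("config needs 'fixture', 'simulate', or 'pileup_dir'")

    pileio.write_catalog(outdir / "catalog.tsv", catalog)
    pileio.write_line_meta(outdir / "lines.tsv", catalog.lines)

    # rates
    rate_df = _stage("rates")(catalog_rates)(catalog)
    rate_df.to_csv(outdir / "rates.tsv", sep="\t")
    counts = catalog.per_line_counts()
    summary["total_events"] = len(catalog.calls)
    summary["total_bps"] = int(counts.m_bps.sum())
    summary["total_indels"] = int(counts.m_indel.sum())
    summary["mean_bps_per_line"] = float(counts.m_bps.mean())
    summary["mean_indels_per_line"] = float(counts.m_indel.mean())
    summary["max_bps_per_line"] = int(counts.m_bps.max())
    summary["max_indels_per_line"] = int(counts.m_indel.max())
    summary["sem_bps_per_line"] = float(counts.m_bps.std(ddof=1) / len(counts) ** 0.5)
    summary["bps_rate_per_site"] = float(rate_df.loc["pooled", "bps_rate"])
    summary["bps_rate_se"] = float(rate_df.loc["pooled", "bps_se"])
    summary["indel_rate_per_site"] = float(rate_df.loc["pooled", "indel_rate"])
    summary["bps_rate_per_genome"] = float(rate_df.loc["pooled", "bps_per_genome"])

    # spectrum
    spec = _stage("spectrum")(summarize_spectrum)(catalog)
    for k, v in spec.percentages().items():
        summary[k] = v
    summary["transitions"] = spec.transitions
    summary["transversions"] = spec.transversions
    summary["ts_tv_pooled"] = spec.ts_tv_pooled
    summary["ts_tv_line_mean"] = spec.ts_tv_line_mean
    summary["nt_lost_per_gen"] = spec.nt_lost_per_gen
    summary["nt_gained_per_gen"] = spec.nt_gained_per_gen
    if spec.indels:
        db = deletion_bias_test(spec)
        summary["deletion_bias_chi2"] = db.chi2
        summary["deletion_bias_p"] = db.p

    # context (needs an actual genome with annotation)
    if genome is not None and genome.genes:
        cd = _stage("context")(coding_distribution_test)(catalog, genome)
        summary["coding_chi2"], summary["coding_p"] = cd.chi2, cd.p
        ns, exp_ns, obs = ns_s_expectation_test(catalog, genome)
        summary["ns_s_chi2"], summary["ns_s_p"] = ns.chi2, ns.p
        summary["expected_ns_fraction"] = exp_ns
        bins = bin_density(catalog, genome, bin_size)
        try:
            tt = terminus_test(bins)
            summary["terminus_t"], summary["terminus_df"] = tt.t, tt.df
            tt_ex = terminus_test(bins, exclude_terminus=True)
            summary["terminus_t_excl"] = tt_ex.t
        except (ZeroDivisionError, ValueError) as exc:
            log.warning("terminus test skipped: %s", exc)

    # MNMs
    for w in windows:
        clusters = detect_mnm(catalog, int(w), genome_size)
        n_clustered = clustered_event_count(clusters)
        summary[f"mnm_clustered_events_w{w}"] = n_clustered
        summary[f"mnm_clustered_pct_w{w}"] = (
            100.0 * n_clustered / len(catalog.calls) if catalog.calls else 0.0
        )
        params = MnmParams.from_counts(
            max(summary["total_bps"], 1), genome_size, catalog.n_lines, int(w)
        )
        summary[f"mnm_expected_p_w{w}"] = mnm_expected_probability(params)

    # recovery report against planted truth
    if truth is not None:
        recall, precision = recovery_report(catalog, truth)
        summary["recall"], summary["precision"] = recall, precision

    # Ne from a provided silent-site alignment
    if config.get("alignment"):
        pi = _stage("ne")(silent_site_pi_from_fasta)(config["alignment"])
        summary["pi_s"] = pi.pi
        summary["ne"] = effective_population_size(pi.pi, summary["bps_rate_per_site"])

    _write_summary(summary, outdir)
    return summary


def _call_from_directory(config: dict, thresholds: CallingThresholds):
    """Calling stage over on-disk pileup/evidence files."""
    directory = Path(config["pileup_dir"])
    if not directory.is_dir():
        raise FileNotFoundError(f"pileup directory not found: {directory}")
    length = int(config["genome_length"])
    counts = {}
    evidence = {}
    for line in pileio.discover_lines(directory):
        paths = pileio.line_file_paths(directory, line)
        counts[line] = (
            pileio.load_pileup_matrix(paths["aligner1"], length),
            pileio.load_pileup_matrix(paths["aligner2"], length),
        )
        evidence[line] = {
            "aligner1": pileio.read_indel_evidence(paths["evidence1"], "aligner1")
            if paths["evidence1"].exists()
            else [],
            "aligner2": pileio.read_indel_evidence(paths["evidence2"], "aligner2")
            if paths["evidence2"].exists()
            else [],
            "paired": pileio.read_indel_evidence(paths["paired"], "paired")
            if paths["paired"].exists()
            else [],
        }
    return call_all_lines(counts, evidence, float(config.get("generations", 1.0)), thresholds)


def recovery_report(catalog, truth) -> tuple[float, float]:
    """Recall and precision of the catalog against non-progenitor truth."""
    truth_keys = {e.key for e in truth.de_novo()}
    call_keys = set()
    for c in catalog.calls:
        if c.mtype == "bps":
            call_keys.add((c.line, c.position, "bps", c.alt))
        else:
            call_keys.add((c.line, c.position, c.mtype, c.size, c.motif))
    tp = len(call_keys & truth_keys)
    recall = tp / len(truth_keys) if truth_keys else 1.0
    precision = tp / len(call_keys) if call_keys else 1.0
    return recall, precision


def _write_summary(summary: dict, outdir: Path) -> None:
    with open(outdir / "summary.tsv", "w") as fh:
        fh.write("field\tvalue\n")
        for k, v in summary.items():
            fh.write(f"{k}\t{v}\n")
    with open(outdir / "summary.txt", "w") as fh:
        fh.write("MA pipeline summary\n")
        fh.write("=" * 40 + "\n")
        for k, v in summary.items():
            if isinstance(v, float):
                fh.write(f"{k:28s} {v:.6g}\n")
            else:
                fh.write(f"{k:28s} {v}\n")
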