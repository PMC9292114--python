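"""End-to-end orchestration of the analysis stages.

Stage order: isoform deduplication -> homeolog pairing -> dS estimation ->
quartet topology filter -> subgenome attribution -> genotype calling ->
sex-determining-region scan -> diversity/selection statistics ->
expression tests -> enrichment -> TMRCA.  Inputs are either files (three
FASTA sets, a VCF, a linkage map, a count matrix with a design file) or a
:class:`~homeoscan.simdata.SimConfig` for fully synthetic runs, in which
case a truth-comparison section is added to the summary.

A single pipeline seed fans out to per-stage child seeds through
``numpy.random.SeedSequence`` so any stage can be rerun in isolation and
two runs of the same configuration are identical.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import codonevol, expr, genotypes, homeology, popstats, quartet, sdrscan, simdata

log = logging.getLogger("homeoscan")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run.

    Exactly one of ``sim`` (synthetic mode) or the input paths must be
    set.  Thresholds default to the values used throughout the package.
    """

    sim: Optional[simdata.SimConfig] = None
    poly_fasta: Optional[str] = None
    prog_fasta: Optional[str] = None
    outgroup_fasta: Optional[str] = None
    vcf: Optional[str] = None
    design: Optional[str] = None
    linkage: Optional[str] = None
    counts: Optional[str] = None
    outdir: str = "homeoscan_out"
    seed: int = 0
    mu: float = 7.5e-9
    quartet_filter: bool = True
    window: int = 20
    boot_reps: int = 1000
    min_score: int = 50
    max_divergence: float = 0.01
    fdr: float = 0.05

    def validate(self) -> None:
        have_files = all(p is not None for p in (self.poly_fasta, self.prog_fasta, self.outgroup_fasta))
        if self.sim is None and not have_files:
            raise ValueError("either synthetic mode (sim) or input FASTA paths are required")
        if self.sim is not None and have_files:
            raise ValueError("synthetic mode and file inputs are mutually exclusive")


@dataclass
class PipelineResult:
    summary: dict
    pairs: pd.DataFrame
    scan_fst: dict[str, sdrscan.ScanSeries] = field(default_factory=dict)
    scan_sbh: dict[str, sdrscan.ScanSeries] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run all stages and write per-stage TSVs plus a JSON summary."""
    t0 = time.perf_counter()
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    seed_scan, seed_misc = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))

    truth: Optional[simdata.TruthTable] = None
    if cfg.sim is not None:
        ds = simdata.simulate_dataset(cfg.sim)
        poly, prog, outg = ds.poly, ds.prog, ds.outgroup
        variants, linkage, expression, truth = ds.variants, ds.linkage, ds.expression, ds.truth
    else:
        poly = homeology.read_fasta(cfg.poly_fasta)
        prog = homeology.read_fasta(cfg.prog_fasta)
        outg = homeology.read_fasta(cfg.outgroup_fasta)
        design = pd.read_csv(cfg.design, sep="\t") if cfg.design else None
        sex_of = dict(zip(design["sample"], design["sex"])) if design is not None else {}
        variants = genotypes.VariantTable.from_vcf(cfg.vcf, sex_of) if cfg.vcf else None
        linkage = pd.read_csv(cfg.linkage, sep="\t") if cfg.linkage else None
        expression = None
        if cfg.counts is not None:
            raw = pd.read_csv(cfg.counts, sep="\t", index_col=0)
            lengths = raw.pop("length")
            expression = expr.ExpressionMatrix(
                counts=raw, lengths=lengths, sex=[sex_of[s] for s in raw.columns]
            )

    summary: dict = {"n_input_transcripts": len(poly)}
    seq_of = {t.id: t.sequence for t in poly + prog + outg}

    # -- dedup ---------------------------------------------------------------
    poly_hits = homeology.all_vs_all(poly)
    red_poly, clusters = homeology.cluster_and_select(poly, cfg.min_score, cfg.max_divergence, hits=poly_hits)
    red_prog, _ = homeology.cluster_and_select(prog, cfg.min_score, cfg.max_divergence)
    summary["n_reduced_transcripts"] = len(red_poly)
    red_ids = {t.id for t in red_poly}
    red_hits = [h for h in poly_hits if h.query in red_ids and h.target in red_ids]

    # -- pairing -------------------------------------------------------------
    prog_hits = homeology.cross_hits(red_poly, red_prog)
    triples = homeology.find_homeolog_pairs(
        red_poly, red_prog, cfg.min_score, poly_hits=red_hits, prog_hits=prog_hits
    )
    summary["n_pairs"] = len(triples)

    # -- dS and quartet classification --------------------------------------
    out_best = {
        q: h.target for q, h in homeology.best_hits(homeology.cross_hits(red_prog, outg)).items()
    }
    pairs: list[codonevol.HomeologPair] = []
    for a, b, t in triples:
        pair = codonevol.HomeologPair(a, b, t)
        try:
            ra = codonevol.ng86(codonevol.align_codons(seq_of[a], seq_of[t]))
            rb = codonevol.ng86(codonevol.align_codons(seq_of[b], seq_of[t]))
            rab = codonevol.ng86(codonevol.align_codons(seq_of[a], seq_of[b]))
        except codonevol.FrameshiftError:
            log.warning("pair (%s, %s) skipped: no usable ORF", a, b)
            continue
        pair.ds_a_prog, pair.ds_b_prog, pair.ds_a_b = ra.dS, rb.dS, rab.dS
        codonevol.assign_subgenome(pair)
        o = out_best.get(t)
        topo = "unresolved"
        if o is not None:
            seqs = [seq_of[a], seq_of[b], seq_of[t], seq_of[o]]
            if len({len(s) for s in seqs}) == 1:
                try:
                    topo = quartet.quartet_topology(seqs).topology
                except ValueError:
                    topo = "unresolved"
        pair.topology_class = _map_topology(topo, pair.subgenome_of_a)
        pairs.append(pair)

    conc = quartet.concordance_summary([p.topology_class for p in pairs]) if pairs else None
    if conc:
        summary["quartet_concordance"] = conc
    retained = [
        p
        for p in pairs
        if (p.topology_class == "expected" if cfg.quartet_filter else p.subgenome_of_a != "unassigned")
    ]
    summary["n_retained_pairs"] = len(retained)

    ds_ab = [p.ds_a_b for p in retained if p.ds_a_b is not None]
    ds_s1 = [min(p.ds_a_prog, p.ds_b_prog) for p in retained if p.ds_a_prog is not None and p.ds_b_prog is not None]
    if ds_ab:
        summary["median_ds_homeolog"] = float(np.median(ds_ab))
        summary["tmrca_subgenomes_generations"] = codonevol.estimate_tmrca(float(np.median(ds_ab)), cfg.mu)
    if ds_s1:
        summary["median_ds_sub1_prog"] = float(np.median(ds_s1))
        summary["tmrca_sub1_prog_generations"] = codonevol.estimate_tmrca(float(np.median(ds_s1)), cfg.mu)

    pair_df = pd.DataFrame(
        [
            {
                "pair": f"{p.member_a}|{p.member_b}",
                "member_a": p.member_a,
                "member_b": p.member_b,
                "progenitor": p.progenitor,
                "ds_a_prog": p.ds_a_prog,
                "ds_b_prog": p.ds_b_prog,
                "ds_a_b": p.ds_a_b,
                "subgenome_of_a": p.subgenome_of_a,
                "topology_class": p.topology_class,
                "sub1": p.sub1_member,
                "sub2": p.sub2_member,
            }
            for p in pairs
        ]
    )
    pair_df.to_csv(os.path.join(cfg.outdir, "homeolog_pairs.tsv"), sep="\t", index=False)

    result = PipelineResult(summary=summary, pairs=pair_df)

    # -- genotypes and SDR scan ---------------------------------------------
    subg_of = {}
    for p in retained:
        if p.sub1_member:
            subg_of[p.sub1_member] = "sub1"
            subg_of[p.sub2_member] = "sub2"
    if variants is not None and linkage is not None:
        called = genotypes.call_genotypes(variants)
        summary["n_sites_retained"] = int(called.n_sites)
        lmap = linkage.set_index("transcript_id")
        stat_rows = []
        for t in called.transcripts():
            if t not in lmap.index:
                continue
            fst = sdrscan.transcript_fst(called, t)
            sbh = sdrscan.sex_biased_heterozygosity(called, t)
            stat_rows.append(
                {
                    "transcript": t,
                    "lg": int(lmap.at[t, "lg"]),
                    "cM": float(lmap.at[t, "cM"]),
                    "region_class": lmap.at[t, "region_class"],
                    "subgenome": subg_of.get(t, "unassigned"),
                    "fst": fst,
                    "sbh": sbh,
                }
            )
        stats_df = pd.DataFrame(stat_rows)
        stats_df.to_csv(os.path.join(cfg.outdir, "sdr_stats.tsv"), sep="\t", index=False)
        result.tables["sdr_stats"] = stats_df
        for sg in ("sub1", "sub2"):
            sub = stats_df[stats_df["subgenome"] == sg]
            auto = sub[sub["region_class"] == "autosomal"]
            for stat in ("fst", "sbh"):
                series = sub.rename(columns={stat: "value"})[["transcript", "lg", "cM", "value"]]
                null = auto.rename(columns={stat: "value"})[["lg", "cM", "value"]]
                try:
                    scan = sdrscan.rolling_scan_with_ci(
                        series, null, window=cfg.window, reps=cfg.boot_reps, seed=seed_scan
                    )
                except ValueError:
                    continue
                scan.windows.to_csv(
                    os.path.join(cfg.outdir, f"scan_{stat}_{sg}.tsv"), sep="\t", index=False
                )
                (result.scan_fst if stat == "fst" else result.scan_sbh)[sg] = scan
                comp = sdrscan.region_compare(sub.rename(columns={stat: "value"}))
                summary.setdefault("region_tests", {})[f"{stat}_{sg}"] = comp.to_dict("records")

        # -- diversity / selection ------------------------------------------
        div_rows = []
        for t in called.transcripts():
            if t not in lmap.index:
                continue
            res = popstats.diversity_stats(called, t, cds=seq_of.get(t))
            if res is None:
                continue
            div_rows.append(
                {
                    "transcript": t,
                    "lg": int(lmap.at[t, "lg"]),
                    "subgenome": subg_of.get(t, "unassigned"),
                    "pi": res.pi,
                    "pi_n": res.pi_n,
                    "pi_s": res.pi_s,
                    "pin_pis": res.pin_pis,
                    "tajimas_d": res.tajimas_d,
                    "S": res.n_segregating,
                }
            )
        div_df = pd.DataFrame(div_rows)
        div_df.to_csv(os.path.join(cfg.outdir, "diversity.tsv"), sep="\t", index=False)
        result.tables["diversity"] = div_df
        summary["subgenome_contrasts"] = {}
        for metric in ("pi", "tajimas_d", "pin_pis"):
            wide = (
                div_df[div_df["subgenome"].isin(["sub1", "sub2"])]
                .groupby(["lg", "subgenome"])[metric]
                .mean()
                .unstack()
            )
            wide = wide.dropna()
            if len(wide) >= 2 and {"sub1", "sub2"} <= set(wide.columns):
                p = popstats.exact_paired_signrank(wide["sub1"], wide["sub2"])
                summary["subgenome_contrasts"][metric] = {
                    "n_lgs": int(len(wide)),
                    "p": p,
                    "mean_sub1": float(wide["sub1"].mean()),
                    "mean_sub2": float(wide["sub2"].mean()),
                }

    # -- expression ----------------------------------------------------------
    if expression is not None:
        tpm_mat = expression.tpm()
        de = expr.nb_de_test(expression.counts, expression.sex, alpha_fdr=cfg.fdr)
        de.to_csv(os.path.join(cfg.outdir, "sex_biased_de.tsv"), sep="\t")
        result.tables["sex_de"] = de
        n_sig = int(de["significant"].sum())
        summary["n_expressed"] = int(len(de))
        summary["n_sex_biased"] = n_sig

        pairs_tbl = pair_df[pair_df["sub1"].notna()][["pair", "sub1", "sub2"]]
        hb = expr.homeolog_bias_test(pairs_tbl, tpm_mat, alpha_fdr=cfg.fdr)
        hb.to_csv(os.path.join(cfg.outdir, "homeolog_bias.tsv"), sep="\t", index=False)
        result.tables["homeolog_bias"] = hb
        summary["homeolog_bias"] = {
            "n_tested": int(len(hb)),
            "sub1_higher": int((hb["direction"] == "sub1_higher").sum()),
            "sub2_higher": int((hb["direction"] == "sub2_higher").sum()),
        }

        sf = expr.subfunctionalization_test(pairs_tbl, tpm_mat, expression.sex, alpha_fdr=cfg.fdr)
        sf.to_csv(os.path.join(cfg.outdir, "subfunctionalization.tsv"), sep="\t", index=False)
        result.tables["subfunc"] = sf
        summary["n_subfunctionalized"] = int((sf["pattern"] != "none").sum())

        if linkage is not None:
            lmap2 = linkage.set_index("transcript_id")
            sub1_ids = [t for t, sg in subg_of.items() if sg == "sub1" and t in lmap2.index and t in de.index]
            if sub1_ids:
                on_lg1 = pd.Series({t: int(lmap2.at[t, "lg"]) == 1 for t in sub1_ids})
                sig = de.loc[sub1_ids, "significant"]
                table = [
                    [int((sig & on_lg1).sum()), int((sig & ~on_lg1).sum())],
                    [int((~sig & on_lg1).sum()), int((~sig & ~on_lg1).sum())],
                ]
                summary["sdr_enrichment"] = {
                    "table": table,
                    "p": expr.fisher_enrichment(table),
                }

    # -- truth comparison (synthetic mode) -----------------------------------
    if truth is not None:
        summary["truth_comparison"] = _truth_comparison(truth, retained, result, cfg.sim.sdr_span)

    log.info("pipeline finished in %.1fs", time.perf_counter() - t0)
    with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    return result


def _map_topology(topo: str, subgenome_of_a: str) -> str:
    """Translate raw quartet topology into a pair-level class."""
    if topo == "ab":
        return "homeolog_sister"
    if topo == "unresolved" or subgenome_of_a == "unassigned":
        return "unresolved"
    lower_is_a = subgenome_of_a == "sub1"
    if topo == "a_prog":
        return "expected" if lower_is_a else "sub2_prog_sister"
    if topo == "b_prog":
        return "expected" if not lower_is_a else "sub2_prog_sister"
    return "unresolved"


def _truth_comparison(truth: simdata.TruthTable, retained, result: PipelineResult, sdr_span) -> dict:
    true_sub = dict(zip(truth.transcripts["transcript"], truth.transcripts["subgenome"]))
    n_ok = n_tot = 0
    same_subgenome_joins = 0
    for p in retained:
        if p.sub1_member is None:
            continue
        ta, tb = true_sub.get(p.sub1_member), true_sub.get(p.sub2_member)
        if ta is None or tb is None:
            continue
        if ta == tb:
            same_subgenome_joins += 1
            continue
        n_tot += 1
        if ta == "sub1" and tb == "sub2":
            n_ok += 1
    out = {
        "n_checked": n_tot,
        "assignment_accuracy": n_ok / n_tot if n_tot else None,
        "same_subgenome_joins": same_subgenome_joins,
    }
    truth_pairs = truth.pairs[~truth.pairs["single_copy"]]
    recovered = {(min(p.member_a, p.member_b), max(p.member_a, p.member_b)) for p in retained}
    truth_set = {(min(r.sub1, r.sub2), max(r.sub1, r.sub2)) for r in truth_pairs.itertuples()}
    out["pair_recovery"] = len(recovered & truth_set) / len(truth_set) if truth_set else None

    for sg in ("sub1", "sub2"):
        scan = result.scan_fst.get(sg)
        if scan is None:
            continue
        flagged, inside = windows_in_span(scan, sdr_span, lg=1)
        out[f"sdr_windows_inside_{sg}"] = inside
        out[f"sdr_windows_flagged_{sg}"] = flagged
        out[f"sdr_flag_rate_{sg}"] = flagged / inside if inside else None
        auto = scan.windows[scan.windows["lg"] != 1]
        out[f"autosomal_flag_rate_{sg}"] = (
            float(auto["elevated"].mean()) if len(auto) else None
        )
    return out


def windows_in_span(scan: sdrscan.ScanSeries, span, lg: int = 1) -> tuple[int, int]:
    """(#flagged, #total) windows whose transcripts all lie within a cM span."""
    lo, hi = span
    w = scan.windows
    sel = w[(w["lg"] == lg) & (w["start_cM"] >= lo) & (w["end_cM"] <= hi)]
    return int(sel["elevated"].sum()), int(len(sel))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
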