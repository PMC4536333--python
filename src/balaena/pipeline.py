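"""End-to-end orchestration: orthology -> QC -> selection -> residues ->
expansion -> summaries, with a reproducible run manifest.

Every stage reads plain-text inputs from a study directory (the layout
written by :func:`balaena.simulate.write_bundle`), writes TSV reports under
the run directory, and contributes record counts to the manifest.  Re-running
with identical config and inputs reproduces identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .codonmodel import CodonAlignment
from .config import validate
from .expansion import (
    assign_expansions,
    root_minimizing_duplications,
    screen_family_expansion,
)
from .genetics import CdsRecord
from .orthology import (
    best_hits,
    cluster_families,
    extract_sgos,
    families_report,
    reciprocal_best_hits,
    rejections_report,
)
from .qc import msa_verdict, pairwise_length_filter
from .residues import residue_density_rank, residue_report_table, unique_residue_columns
from .seqio import read_fasta, read_hit_table, write_tsv
from .selection import (
    acceleration_ratio,
    branch_site_test,
    call_positive_selection,
    neb_site_posteriors,
    pairwise_ml_dnds,
    rank_acceleration,
)
from .summary import coverage_table, read_te_counts, shannon_index
from .trees import PhyloTree

log = logging.getLogger("balaena")


class InputError(FileNotFoundError):
    pass


class StageError(RuntimeError):
    pass


def _require(path: Path) -> Path:
    if not path.exists():
        raise InputError(f"missing input: {path}")
    return path


def _species_of(gene_id: str) -> str:
    return gene_id.split("|", 1)[0]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict, input_dir: str | Path, out_dir: str | Path) -> dict:
    """Run the configured stages; returns the manifest dict.

    Raises :class:`InputError` for missing inputs and :class:`StageError`
    when a stage fails (partial outputs are retained and the manifest marks
    the failure).
    """
    cfg = validate(config)
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    inputs = {
        p.name: _checksum(p)
        for p in sorted(input_dir.rglob("*"))
        if p.is_file()
    }
    manifest: dict = {
        "version": __version__,
        "config": cfg,
        "input_checksums": inputs,
        "stages": {},
        "status": "running",
    }

    state: dict = {}
    try:
        for stage in cfg["stages"]:
            t0 = time.time()
            log.info("stage %s: start", stage)
            counts = _STAGES[stage](cfg, input_dir, out_dir, state)
            manifest["stages"][stage] = {
                "counts": counts,
                "seconds": round(time.time() - t0, 2),
            }
            log.info("stage %s: done in %.1fs", stage, time.time() - t0)
    except InputError:
        manifest["status"] = "input_error"
        _write_manifest(manifest, out_dir)
        raise
    except Exception as exc:
        manifest["status"] = f"failed: {exc}"
        _write_manifest(manifest, out_dir)
        raise StageError(str(exc)) from exc
    manifest["status"] = "ok"
    manifest["seconds"] = round(time.time() - t_start, 2)
    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    tmp = out_dir / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    os.replace(tmp, out_dir / "manifest.json")


# ---------------------------------------------------------------------------
# stages


def stage_orthology(cfg, input_dir: Path, out_dir: Path, state: dict) -> dict:
    hits = read_hit_table(_require(input_dir / "hits.tsv"))
    cds_records = read_fasta(_require(input_dir / "cds.fasta"))
    cds_by_gene = {
        r.id: CdsRecord(gene_id=r.id, species=_species_of(r.id), sequence=r.sequence)
        for r in cds_records
    }
    cutoff = cfg["orthology"]["evalue_cutoff"]

    hits = hits.assign(
        _qs=hits["query_id"].map(_species_of), _ss=hits["subject_id"].map(_species_of)
    )
    hits = hits[hits["_qs"] != hits["_ss"]]
    bh: dict[tuple[str, str], dict[str, str]] = {}
    for (qs, ss), group in hits.groupby(["_qs", "_ss"]):
        bh[(qs, ss)] = best_hits(group.drop(columns=["_qs", "_ss"]), cutoff)
    pairs = []
    for (qs, ss) in sorted(bh):
        if qs < ss and (ss, qs) in bh:
            pairs.extend(reciprocal_best_hits(bh[(qs, ss)], bh[(ss, qs)]))
    families = cluster_families(pairs, sorted(cds_by_gene), _species_of)
    sgos, rejections = extract_sgos(
        families, cds_by_gene,
        min_species_exclusive=cfg["orthology"]["min_species_exclusive"],
    )
    write_tsv(families_report(families), out_dir / "families.tsv")
    write_tsv(rejections_report(rejections), out_dir / "rejections.tsv")
    write_tsv(
        pd.DataFrame(
            [
                (s.family_id, sp, g)
                for s in sgos
                for sp, g in sorted(s.gene_by_species.items())
            ],
            columns=["family_id", "species", "gene_id"],
        ),
        out_dir / "sgos.tsv",
    )
    state["cds_by_gene"] = cds_by_gene
    state["families"] = families
    state["sgos"] = sgos
    return {
        "rbh_pairs": len(pairs),
        "families": len(families),
        "sgos_kept": len(sgos),
        "sgos_rejected": len(rejections),
    }


def _sgo_alignment(sgo, cds_by_gene) -> CodonAlignment:
    named = [
        (species, cds_by_gene[gene].sequence)
        for species, gene in sorted(sgo.gene_by_species.items())
    ]
    return CodonAlignment.from_sequences(named)


def stage_qc(cfg, input_dir: Path, out_dir: Path, state: dict) -> dict:
    if "sgos" not in state:
        stage_orthology(cfg, input_dir, out_dir, state)
    focal = {cfg["focal_species"], cfg["sister_species"]}
    rows = []
    verdicts = {}
    for sgo in state["sgos"]:
        named = [
            (sp, cds_by.sequence)
            for sp, cds_by in (
                (s, state["cds_by_gene"][g])
                for s, g in sorted(sgo.gene_by_species.items())
            )
        ]
        present_focal = focal & {n for n, _ in named}
        verdict = msa_verdict(
            named,
            present_focal or {named[0][0]},
            max_insert_bp=cfg["qc"]["max_insert_bp"],
            min_focal_fraction=cfg["qc"]["min_focal_fraction"],
            alignment_id=sgo.family_id,
        )
        verdicts[sgo.family_id] = verdict
        for f in verdict.filters:
            rows.append((sgo.family_id, f.name, f.passed, f.detail))
    write_tsv(
        pd.DataFrame(rows, columns=["family_id", "filter", "passed", "detail"]),
        out_dir / "qc.tsv",
    )
    state["qc_verdicts"] = verdicts
    n_passed = sum(1 for v in verdicts.values() if v.passed)
    return {"sgos_tested": len(verdicts), "passed": n_passed,
            "failed": len(verdicts) - n_passed}


def stage_selection(cfg, input_dir: Path, out_dir: Path, state: dict) -> dict:
    if "qc_verdicts" not in state:
        stage_qc(cfg, input_dir, out_dir, state)
    species_tree = PhyloTree.from_file(_require(input_dir / "species_tree.nwk"))
    sel = cfg["selection"]
    site_model = sel["site_dialect"]
    focal = cfg["focal_species"]
    fit_rows, lrt_rows, site_rows, call_rows = [], [], [], []
    pw_rows, accel = [], {}
    n_positive = 0
    for sgo in state["sgos"]:
        aln = _sgo_alignment(sgo, state["cds_by_gene"])
        if focal not in aln.taxa:
            continue
        tree = species_tree.pruned_to(set(aln.taxa))
        tree.set_foreground(focal)
        suite = branch_site_test(
            aln, tree, site_model=site_model, start_omegas=sel["start_omegas"]
        )
        m0, site, alt, null = suite.m0, suite.site, suite.a, suite.a_null
        for fit in (m0, site, alt, null):
            fit_rows.append(
                (sgo.family_id, fit.model, round(fit.lnl, 4), fit.n_free_params,
                 round(fit.params.kappa, 4),
                 ";".join(f"{w:.4f}" for w in fit.params.foreground_omegas),
                 ";".join(f"{p:.4f}" for p in fit.params.class_props),
                 fit.converged)
            )
        lrt_site = suite.lrt_vs_site
        lrt_null = suite.lrt_vs_null
        for r in (lrt_site, lrt_null):
            lrt_rows.append(
                (sgo.family_id, r.null_model, r.alt_model, round(r.statistic, 4),
                 r.df, r.p_value)
            )
        posterior = neb_site_posteriors(
            alt, aln, pp_threshold=sel["pp_threshold"], focal_taxon=focal
        )
        for entry in posterior.flagged:
            site_rows.append(
                (sgo.family_id, entry["alignment_column"],
                 entry.get("focal_position"), round(entry["pp"], 4))
            )
        call = call_positive_selection(
            lrt_site, lrt_null, alt,
            qc_passed=state["qc_verdicts"][sgo.family_id].passed,
            alpha=sel["alpha"], gene_id=sgo.family_id,
        )
        n_positive += call.positive
        call_rows.append(
            (sgo.family_id, call.positive, ";".join(call.failed_criteria),
             call.p_vs_site_null, call.p_vs_a_null, round(call.omega2, 4))
        )
        accel[sgo.family_id] = _pairwise_for_sgo(cfg, sgo, state, pw_rows)

    write_tsv(pd.DataFrame(fit_rows, columns=[
        "family_id", "model", "lnl", "n_free_params", "kappa",
        "foreground_omegas", "class_props", "converged"]),
        out_dir / "fits.tsv")
    write_tsv(pd.DataFrame(lrt_rows, columns=[
        "family_id", "null_model", "alt_model", "statistic", "df", "p_value"]),
        out_dir / "lrts.tsv")
    write_tsv(pd.DataFrame(site_rows, columns=[
        "family_id", "alignment_column", "focal_position", "pp"]),
        out_dir / "sites.tsv")
    write_tsv(pd.DataFrame(call_rows, columns=[
        "family_id", "positive", "failed_criteria", "p_vs_site_model",
        "p_vs_a_null", "omega2"]),
        out_dir / "selection_calls.tsv")
    write_tsv(pd.DataFrame(pw_rows, columns=[
        "family_id", "species_a", "species_b", "dn", "ds", "omega", "flags"]),
        out_dir / "pairwise_dnds.tsv")
    ranked = rank_acceleration(accel, top_fraction=sel["top_fraction"])
    write_tsv(pd.DataFrame(ranked), out_dir / "acceleration.tsv")
    return {
        "families_tested": len(call_rows),
        "positive_calls": n_positive,
        "flagged_sites": len(site_rows),
        "pairwise_estimates": len(pw_rows),
    }


def _pairwise_for_sgo(cfg, sgo, state, pw_rows) -> float | None:
    """Pairwise ML omegas (focal-sister, sister-ref1, sister-ref2) and the
    acceleration ratio of the focal pair against the reference pairs."""
    focal, sister = cfg["focal_species"], cfg["sister_species"]
    refs = cfg["reference_species"]
    seqs = {
        sp: state["cds_by_gene"][g].sequence
        for sp, g in sgo.gene_by_species.items()
    }
    omegas = []
    for pair in [(focal, sister), (sister, refs[0]), (sister, refs[1])]:
        a, b = pair
        if a not in seqs or b not in seqs:
            omegas.append(None)
            continue
        keep, _ = pairwise_length_filter(
            seqs[a], seqs[b], cfg["qc"]["min_pairwise_fraction"]
        )
        if not keep:
            omegas.append(None)
            continue
        res = pairwise_ml_dnds(
            seqs[a], seqs[b], gene_id=sgo.family_id, species_a=a, species_b=b
        )
        pw_rows.append(
            (sgo.family_id, a, b,
             None if res.dn is None else round(res.dn, 5),
             None if res.ds is None else round(res.ds, 5),
             None if res.omega is None else round(res.omega, 4),
             ";".join(res.flags))
        )
        omegas.append(res.omega)
    return acceleration_ratio(*omegas)


def stage_residues(cfg, input_dir: Path, out_dir: Path, state: dict) -> dict:
    aln_dir = _require(input_dir / "residue_alignments")
    focal = cfg["focal_species"]
    reports = []
    for path in sorted(aln_dir.glob("*.faa")):
        msa = [(r.id, r.sequence) for r in read_fasta(path)]
        reports.append(
            unique_residue_columns(
                msa, focal,
                max_unknown_others=cfg["residues"]["max_unknown_others"],
                require_others_identical=cfg["residues"]["require_others_identical"],
                protein_id=path.stem,
            )
        )
    ranked = residue_density_rank(reports, cfg["residues"]["top_fraction"])
    write_tsv(residue_report_table(ranked), out_dir / "residues.tsv")
    return {
        "proteins_scanned": len(ranked),
        "unique_residues": sum(r.u for r in ranked),
        "top_flagged": sum(r.top5 for r in ranked),
    }


def stage_expansion(cfg, input_dir: Path, out_dir: Path, state: dict) -> dict:
    species_tree = PhyloTree.from_file(_require(input_dir / "species_tree.nwk"))
    tree_dir = _require(input_dir / "gene_trees")
    proteins = {
        r.id: r.sequence for r in read_fasta(_require(input_dir / "proteins.fasta"))
    }
    counts_path = input_dir / "read_counts.tsv"
    read_counts = (
        pd.read_csv(counts_path, sep="\t") if counts_path.exists() else None
    )
    exp = cfg["expansion"]
    recs, pair_rows = [], []
    n_candidates = n_kept = 0
    for path in sorted(tree_dir.glob("*.nwk")):
        gene_tree = PhyloTree.from_file(path)
        gene_tree = root_minimizing_duplications(gene_tree, species_tree)
        rec, report = screen_family_expansion(
            path.stem, gene_tree, species_tree, proteins, read_counts,
            focal_species=cfg["focal_species"],
            min_diff=exp["min_diff_pct"], max_diff=exp["max_diff_pct"],
            min_reads=exp["min_reads"],
        )
        recs.append(rec)
        if report is not None:
            n_candidates += 1
            n_kept += report.passes_identity_band
            for pair in report.duplicate_pairs:
                pair_rows.append((report.family_id, report.lineage, pair["gene_a"],
                                  pair["gene_b"], round(pair["percent_diff"], 3),
                                  pair["band_keep"],
                                  pair.get("expressed_a"), pair.get("expressed_b")))
    write_tsv(assign_expansions(recs, species_tree), out_dir / "expansion_branch_counts.tsv")
    write_tsv(pd.DataFrame(pair_rows, columns=[
        "family_id", "lineage", "gene_a", "gene_b", "percent_diff",
        "band_keep", "expressed_a", "expressed_b"]),
        out_dir / "expansions.tsv")
    return {
        "gene_trees": len(recs),
        "total_duplications": sum(r.n_duplications for r in recs),
        "focal_candidates": n_candidates,
        "focal_kept_band": n_kept,
    }


def stage_summary(cfg, input_dir: Path, out_dir: Path, state: dict) -> dict:
    te_counts = read_te_counts(_require(input_dir / "te_counts.tsv"))
    h = shannon_index(te_counts)
    write_tsv(
        pd.DataFrame(
            [("shannon_index_nats", round(h, 3)), ("n_classes", len(te_counts))],
            columns=["statistic", "value"],
        ),
        out_dir / "te_summary.tsv",
    )
    libs = pd.read_csv(_require(input_dir / "coverage.tsv"), sep="\t")
    table = coverage_table(
        list(zip(libs.iloc[:, 0], libs.iloc[:, 1])),
        cfg["summary"]["genome_size_gb"],
    )
    write_tsv(table, out_dir / "coverage_summary.tsv")
    return {
        "te_classes": len(te_counts),
        "shannon_index": round(h, 3),
        "total_coverage_x": float(table.iloc[-1]["coverage_x"]),
    }


_STAGES = {
    "orthology": stage_orthology,
    "qc": stage_qc,
    "selection": stage_selection,
    "residues": stage_residues,
    "expansion": stage_expansion,
    "summary": stage_summary,
}
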