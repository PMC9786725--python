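"""End-to-end orchestration: classify -> extract -> scan -> stats ->
hr distances -> consensus, driven by a single config mapping.

Each run writes TSV tables, a versioned JSON summary and figures into an
output directory; every artefact carries the sha256 hash of the
canonicalised config for provenance.  Stages degrade gracefully: without
a TSS table only classification and hr analysis run; without RPKM the
scan-only mode runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from baculoprom import (
    DEFAULT_SCHEME,
    MotifQuery,
    UPSTREAM_OCTAMER,
    DOWNSTREAM_OCTAMER,
    classify_orfs,
    compare_classes,
    class_genome_map,
    consensus_string,
    distance_table,
    extract_5utr,
    extract_tis_flank,
    extract_tss_flank,
    extract_upstream,
    genome_scan,
    motif_presence_by_class,
    nearest_tss,
    per_region_match_table,
    read_genbank,
    read_tables,
    shared_octamers,
    stack_regions,
    write_regions_fasta,
)
from baculoprom.consensus import flank_positions

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1

DEFAULT_CONFIG = {
    "genbank": None,
    "rpkm_table": None,
    "tss_table": None,
    "hr_table": None,
    "upstream_window": 225,
    "tis_flank": (10, 6),
    "tss_flank": (15, 15),
    "octamers": [UPSTREAM_OCTAMER, DOWNSTREAM_OCTAMER],
    "max_mismatches": 2,
    "test_method": "welch",
    "plurality_threshold": 0.5,
    "secondary_threshold": 0.25,
    "outdir": "baculoprom_report",
}


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def run_pipeline(config: dict) -> dict:
    """Run every applicable stage; returns the JSON-style summary dict."""
    cfg = {**DEFAULT_CONFIG, **config}
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    h = config_hash(cfg)
    notices: list = []

    genome = cfg.get("genome") or read_genbank(cfg["genbank"])
    rpkm, tss, hr_rows = {}, list(getattr(genome, "tss", [])), []
    if any(cfg.get(k) for k in ("rpkm_table", "tss_table", "hr_table")):
        rpkm, tss_read, hr_rows = read_tables(
            cfg.get("rpkm_table"), cfg.get("tss_table"), cfg.get("hr_table"),
            known_orf_ids={o.orf_id for o in genome.orfs},
        )
        if tss_read:
            tss = tss_read
    if cfg.get("rpkm") is not None:
        rpkm = cfg["rpkm"]
    if cfg.get("tss") is not None:
        tss = cfg["tss"]
    if hr_rows:  # table wins over annotation on conflict
        if genome.hrs:
            notices.append("hr table supplied; overriding GenBank hr annotation")
        genome.hrs = hr_rows

    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "config_hash": h,
        "genome": {"accession": genome.accession, "length_nt": genome.length_nt,
                   "circular": genome.is_circular, "n_orfs": len(genome.orfs),
                   "n_hrs": len(genome.hrs)},
        "notices": notices,
    }

    # ---- classification ------------------------------------------------
    classified = []
    if rpkm:
        for o in genome.orfs:
            o.rpkm = rpkm.get(o.orf_id, o.rpkm)
        with_rpkm = [o for o in genome.orfs if o.rpkm is not None]
        tally, classified, excluded = classify_orfs(with_rpkm, DEFAULT_SCHEME)
        pd.DataFrame(
            [{"orf_id": o.orf_id, "rpkm": o.rpkm, "class": o.expr_class}
             for o in classified]
        ).to_csv(outdir / "classes.tsv", sep="\t", index=False)
        summary["classification"] = {"tally": dict(tally),
                                     "n_unclassified": len(excluded)}
    else:
        notices.append("no RPKM data: classification skipped (scan-only mode)")

    # ---- region extraction ---------------------------------------------
    regions: dict = {"utr5": [], "upstream": [], "tis_flank": [], "tss_flank": []}
    anchored = classified if classified else genome.orfs
    if tss:
        up_w = cfg["upstream_window"]
        tis_u, tis_d = cfg["tis_flank"]
        tss_u, tss_d = cfg["tss_flank"]
        for orf in anchored:
            t = nearest_tss(orf, tss)
            if t is None:
                continue
            regions["utr5"].append(extract_5utr(genome, orf, t))
            regions["upstream"].append(extract_upstream(genome, orf, t, window=up_w))
            regions["tis_flank"].append(extract_tis_flank(genome, orf, tis_u, tis_d))
            regions["tss_flank"].append(extract_tss_flank(genome, orf, t, tss_u, tss_d))
        for kind, rs in regions.items():
            nonempty = [r for r in rs if r.sequence]
            if nonempty:
                write_regions_fasta(nonempty, outdir / f"regions_{kind}.fasta")
        summary["regions"] = {k: len(v) for k, v in regions.items()}
    else:
        notices.append("no TSS annotations: extraction/scan/consensus on regions skipped")

    # ---- motif scanning -------------------------------------------------
    scans = {}
    for octamer in cfg["octamers"]:
        q = MotifQuery(octamer, cfg["max_mismatches"], "both")
        gs = genome_scan(genome, q)
        entry = {"genome_total": gs.total_matches,
                 "per_strand": list(gs.per_strand),
                 "rate_per_kbp": round(gs.rate_per_kbp, 3)}
        if regions["upstream"]:
            table, hist, by_region = per_region_match_table(regions["upstream"], q)
            table.to_csv(outdir / f"matches_{octamer}.tsv", sep="\t", index=False)
            entry["upstream_regions"] = {
                "total_matches": int(table["n_matches"].sum()),
                "histogram": {str(k): round(v, 4) for k, v in hist.items()},
                "shared": shared_octamers(by_region),
            }
        scans[octamer] = entry
    summary["scans"] = scans

    if tss and classified:
        presence = motif_presence_by_class(tss, classified)
        presence.to_csv(outdir / "motif_presence.tsv", sep="\t", index=False)
        summary["motif_presence"] = presence.to_dict(orient="records")

    # ---- composition stats ----------------------------------------------
    if regions["utr5"] and classified:
        from baculoprom.composition_stats import class_composition_table

        comp = class_composition_table(genome, classified, tss)
        comp.to_csv(outdir / "utr_composition.tsv", sep="\t", index=False)
        tests = {}
        for col in ("utr_length", "at_content"):
            vals = {c: g[col].dropna().tolist() for c, g in comp.groupby("class")}
            try:
                tdf = compare_classes(vals, method=cfg["test_method"])
                tdf.to_csv(outdir / f"tests_{col}.tsv", sep="\t", index=False)
                tests[col] = int((tdf["pvalue"] < 0.05).sum())
            except ValueError as exc:
                notices.append(f"composition tests for {col} skipped: {exc}")
        summary["composition"] = {"n_orfs": len(comp),
                                  "significant_pairs": tests}

    # ---- hr distances & genome map ---------------------------------------
    if genome.hrs:
        table, nearest = distance_table(genome, orfs=classified or None)
        table.to_csv(outdir / "hr_distances.tsv", sep="\t", index=False)
        nearest.to_csv(outdir / "hr_nearest.tsv", sep="\t", index=False)
        summary["hr"] = {"n_pairs": len(table)}
    if classified:
        class_genome_map(genome, classified, path=outdir / "genome_map.png")

    # ---- consensus --------------------------------------------------------
    if regions["tis_flank"] and classified:
        cons_out = {}
        class_of = {o.orf_id: o.expr_class for o in classified}
        for kind, (u, d) in (("tis_flank", cfg["tis_flank"]),
                             ("tss_flank", cfg["tss_flank"])):
            per_class: dict = {}
            for r in regions[kind]:
                cls = class_of.get(r.orf_id)
                if cls:
                    per_class.setdefault(cls, []).append(r)
            for cls, rs in sorted(per_class.items()):
                if len(rs) < 2:
                    continue
                mat = stack_regions(rs, kind)
                res = consensus_string(
                    mat, cfg["plurality_threshold"], cfg["secondary_threshold"],
                    label=cls, anchor_kind=kind.split("_")[0],
                    positions=flank_positions(u, d),
                )
                cons_out[f"{kind}:{cls}"] = res.consensus
        summary["consensus"] = cons_out

    summary["notices"] = notices
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
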