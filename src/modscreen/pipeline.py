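"""End-to-end orchestration: cohort -> filters -> enrichment -> shared signature.

One run reads a declarative YAML config naming the inputs (multi-sample VCF,
annotation TSV, cohort table, GMT collections), the analysis designs, and
the parameters (consensus threshold ``k``, significance level ``alpha``,
missing-genotype policy, background-universe policy).  For every analysis it
writes per-subgroup surviving-variant TSVs, gene lists and enrichment
tables, the cross-subgroup shared signature, and a JSON manifest recording
resolved parameters, input hashes and stage-wise counts.  Re-running an
identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cohort import AnalysisDesign, build_design, load_cohort_table
from .enrichment import (
    EnrichmentResult,
    GeneSetCollection,
    SharedSignature,
    enrich,
    intersect_subgroups,
    read_gmt,
)
from .segregation import evaluate_subgroup, genes_per_subgroup
from .variants import join_variants, read_annotations, read_genotypes

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A run-level failure, reported with its analysis/subgroup context."""


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    vcf: Path
    annotations: Path
    cohort: Path
    gene_sets: list[Path]
    analyses: list[dict]
    k: int = 3
    alpha: float = 0.05
    missing_policy: str = "strict"
    universe: str = "observed"  # "observed" or a universe file path
    universe_file: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        base = path.parent

        def resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        inputs = doc.get("inputs", {})
        params = doc.get("parameters", {})
        universe = str(params.get("universe", "observed"))
        cfg = cls(
            vcf=resolve(inputs["vcf"]),
            annotations=resolve(inputs["annotations"]),
            cohort=resolve(inputs["cohort"]),
            gene_sets=[resolve(p) for p in inputs.get("gene_sets", [])],
            analyses=doc.get("analyses", []),
            k=int(params.get("k", 3)),
            alpha=float(params.get("alpha", 0.05)),
            missing_policy=str(params.get("missing_policy", "strict")),
            universe="observed" if universe == "observed" else "file",
            universe_file=None if universe == "observed" else resolve(universe),
        )
        for p in [cfg.vcf, cfg.annotations, cfg.cohort, *cfg.gene_sets]:
            if not Path(p).exists():
                raise PipelineError(f"input file does not exist: {p}")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_variants_tsv(path: Path, survivors) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\trsid\tgene\trule\tn_damaging_votes\tmaf\n")
        for r in survivors:
            ann = r.annotation
            maf = "" if ann.maf is None else repr(ann.maf)
            fh.write(
                f"{r.key.chrom}\t{r.key.pos}\t{r.key.ref}\t{r.key.alt}\t"
                f"{ann.rsid or ''}\t{ann.gene_symbol}\t{r.rule}\t"
                f"{r.verdict.n_damaging_votes}\t{maf}\n"
            )


def _write_enrichment_tsv(path: Path, results: list[EnrichmentResult]) -> None:
    with open(path, "w") as fh:
        fh.write("set_id\tname\tk\tn\tK\tN\tp\tq\n")
        for r in results:
            fh.write(f"{r.set_id}\t{r.name}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                     f"{r.p:.6g}\t{r.q:.6g}\n")


def _write_shared_tsv(path: Path, sig: SharedSignature) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tvalue\n")
        for g in sig.shared_genes:
            fh.write(f"shared_gene\t{g}\n")
        for s in sig.shared_sets:
            fh.write(f"shared_set\t{s}\n")
        for s in sig.significant_shared_sets:
            fh.write(f"significant_shared_set\t{s}\n")


def run_analysis(config: RunConfig, outdir: str | Path) -> Path:
    """Execute every configured analysis and write outputs under ``outdir``.

    On any error the partially written output directory is removed before
    the error is re-raised with its analysis/subgroup context.
    """
    outdir = Path(outdir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config, outdir)
    except Exception:
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        raise


def _run(config: RunConfig, outdir: Path) -> Path:
    cohort = load_cohort_table(config.cohort)
    gm = read_genotypes(config.vcf)
    annotations = read_annotations(config.annotations)
    joined = join_variants(gm, annotations)
    collections = [read_gmt(p) for p in config.gene_sets]

    if config.universe == "observed":
        background = sorted({jv.annotation.gene_symbol.upper() for jv in joined})
    else:
        background = sorted(
            {g.strip().upper()
             for g in Path(config.universe_file).read_text().split()
             if g.strip()}
        )
    logger.info("background universe: %d genes (%s)", len(background), config.universe)

    manifest: dict = {
        "tool": {"name": "modscreen", "version": __version__},
        "parameters": {
            "k": config.k,
            "alpha": config.alpha,
            "missing_policy": config.missing_policy,
            "universe": config.universe,
            "universe_size": len(background),
            "fdr_method": "benjamini-hochberg",
        },
        "inputs": {
            str(p): _sha256(Path(p))
            for p in [config.vcf, config.annotations, config.cohort,
                      *config.gene_sets]
        },
        "analyses": {},
    }

    for block in config.analyses:
        name = block.get("name", block["phenotype"])
        try:
            design = build_design(
                cohort,
                block["phenotype"],
                block["positive_subgroups"],
                block["negatives"],
                analysis_name=name,
                min_control_age=int(block.get("min_control_age", 40)),
            )
            _run_one_analysis(
                design, gm, annotations, joined, collections, background,
                config, outdir / name, manifest,
            )
        except Exception as exc:
            raise PipelineError(f"analysis {name!r}: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    tmp = manifest_path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    tmp.replace(manifest_path)
    return outdir


def _run_one_analysis(design, gm, annotations, joined, collections, background,
                      config: RunConfig, adir: Path, manifest: dict) -> None:
    adir.mkdir(parents=True, exist_ok=True)
    per_genes: dict[str, list[str]] = {}
    per_enrich: dict[str, list[EnrichmentResult]] = {}
    counts: dict[str, dict] = {}

    for sg in design.positive_subgroups:
        results = evaluate_subgroup(
            gm, annotations, design, sg, k=config.k,
            missing_policy=config.missing_policy, joined=joined,
        )
        segregating = [r for r in results if r.passed]
        survivors = [r for r in segregating if r.verdict.is_damaging]
        genes = genes_per_subgroup(survivors)
        logger.info(
            "%s/%s: %d variants -> %d annotated -> %d segregating -> "
            "%d damaging -> %d genes",
            design.analysis_name, sg.subgroup_id, gm.n_variants, len(results),
            len(segregating), len(survivors), len(genes),
        )
        counts[sg.subgroup_id] = {
            "variants_total": gm.n_variants,
            "annotated": len(results),
            "segregating": len(segregating),
            "surviving": len(survivors),
            "genes": len(genes),
        }
        _write_variants_tsv(adir / f"{sg.subgroup_id}_variants.tsv", survivors)
        (adir / f"{sg.subgroup_id}_genes.txt").write_text(
            "".join(f"{g}\n" for g in genes)
        )
        per_genes[sg.subgroup_id] = genes
        enr: list[EnrichmentResult] = []
        for coll in collections:
            enr.extend(enrich(genes, coll, background))
        _write_enrichment_tsv(adir / f"{sg.subgroup_id}_enrichment.tsv", enr)
        per_enrich[sg.subgroup_id] = enr

    if len(per_genes) >= 2:
        sig = intersect_subgroups(per_genes, per_enrich, alpha=config.alpha)
    else:
        only = next(iter(per_genes.values()), [])
        sig = SharedSignature(
            shared_genes=tuple(g.upper() for g in only),
            shared_sets=tuple(sorted({r.set_id for r in
                                      next(iter(per_enrich.values()), [])
                                      if r.k >= 1})),
            significant_shared_sets=(),
            alpha=config.alpha,
        )
    _write_shared_tsv(adir / "shared_signature.tsv", sig)
    manifest["analyses"][design.analysis_name] = {
        "subgroups": counts,
        "shared_genes": list(sig.shared_genes),
        "n_shared_sets": len(sig.shared_sets),
        "n_significant_shared_sets": len(sig.significant_shared_sets),
    }


def report(outdir: str | Path) -> str:
    """Human-readable summary of a completed run (shared genes and pathways)."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise PipelineError(f"no manifest.json under {outdir}: run not completed")
    manifest = json.loads(manifest_path.read_text())

    lines: list[str] = []
    for name, block in manifest.get("analyses", {}).items():
        lines.append(f"analysis: {name}")
        shared = block.get("shared_genes", [])
        lines.append(
            "  shared genes ({}): {}".format(
                len(shared), ", ".join(shared) if shared else "none"
            )
        )
        shared_tsv = outdir / name / "shared_signature.tsv"
        shared_sets: list[str] = []
        significant: list[str] = []
        if shared_tsv.exists():
            for line in shared_tsv.read_text().splitlines()[1:]:
                kind, value = line.split("\t")
                if kind == "shared_set":
                    shared_sets.append(value)
                elif kind == "significant_shared_set":
                    significant.append(value)
        lines.append(
            "  shared pathways ({}): {}".format(
                len(shared_sets), ", ".join(shared_sets) if shared_sets else "none"
            )
        )
        lines.append(
            "  significant shared pathways ({}): {}".format(
                len(significant), ", ".join(significant) if significant else "none"
            )
        )
        for sg, c in block.get("subgroups", {}).items():
            lines.append(
                f"  {sg}: {c['variants_total']} variants -> "
                f"{c['segregating']} segregating -> {c['surviving']} damaging -> "
                f"{c['genes']} genes"
            )
    if not lines:
        lines.append("no analyses in manifest")
    return "\n".join(lines) + "\n"
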