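"""End-to-end pipeline orchestration with reproducible provenance.

``RunConfig`` holds every stage's parameters (defaults are the
pipeline's standard settings: filter at min_len 40 / mean quality 15 /
entropy 60, one million sampled pairs, three replicates, genome-size
alignment filters 60 bp / 70%).  ``run_pipeline`` wires the stages
together and writes a manifest of all seeds and parameters so a run
can be reproduced byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from repeatscape import annotate, ecology, genomesize, preprocess, seqio


@dataclass
class RunConfig:
    reads1: str = ""
    reads2: str = ""
    library: str = ""
    out_dir: str = "repeatscape_out"
    # filter stage
    min_len: int = 40
    min_mean_qual: float = 15.0
    entropy_threshold: float = 60.0
    trim_ns_right: int = 10
    max_n_percent: float = 20.0
    # optional contaminant screen
    contaminants: Optional[str] = None
    screen_min_identity: float = 90.0
    screen_min_len: int = 50
    # sampling / clustering / annotation
    sample_pairs: int = 1_000_000
    replicates: int = 3
    seed: int = 1
    cluster_min_len: int = 55
    cluster_min_identity: float = 90.0
    cluster_min_coverage: float = 0.55
    merge_links: int = 100
    # RAD fitting
    rad_scale: float = 1e6
    # optional genome size stage
    transcripts: Optional[str] = None
    ploidy: int = 1
    gs_min_aln_len: int = 60
    gs_min_identity: float = 70.0
    gs_trim_top: float = 0.10

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _preflight(config: RunConfig) -> None:
    problems = []
    for label, path in [("reads1", config.reads1), ("reads2", config.reads2),
                        ("library", config.library)]:
        if not path:
            problems.append(f"{label} not set")
        elif not Path(path).exists():
            problems.append(f"{label} file missing: {path}")
    for label, path in [("contaminants", config.contaminants),
                        ("transcripts", config.transcripts)]:
        if path and not Path(path).exists():
            problems.append(f"{label} file missing: {path}")
    if problems:
        raise FileNotFoundError("; ".join(problems))


def run_pipeline(config: RunConfig) -> Path:
    """Filter -> screen -> replicated sample/cluster/annotate -> RAD/diversity.

    Returns the output directory; writes composition.tsv, radfit.json,
    diversity.json, optional genome_size.json and a manifest.json with
    the parameter hash and seeds used.
    """
    _preflight(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    policy = preprocess.FilterPolicy(
        min_len=config.min_len, min_mean_qual=config.min_mean_qual,
        entropy_threshold=config.entropy_threshold,
        trim_ns_right=config.trim_ns_right, max_n_percent=config.max_n_percent,
    )
    raw_pairs = list(seqio.read_fastq(config.reads1, paired_with=config.reads2))
    pairs, reject_log = preprocess.filter_reads(raw_pairs, policy)
    if config.contaminants:
        contaminants = list(seqio.read_fasta(config.contaminants))
        pairs, dropped = preprocess.screen_contaminants(
            pairs, contaminants, config.screen_min_identity, config.screen_min_len
        )
        reject_log["contaminant"] = dropped
    library = seqio.read_repeat_library(config.library)
    k = min(config.sample_pairs, len(pairs))
    seeds = annotate._spawn_seeds(config.seed, config.replicates)
    table = annotate.replicate_composition(
        pairs, library, k, replicates=config.replicates, seeds=seeds,
        min_len=config.cluster_min_len, min_identity=config.cluster_min_identity,
        min_coverage=config.cluster_min_coverage, merge_links=config.merge_links,
    )
    table.to_csv(out / "composition.tsv", sep="\t")

    fams = table.index.difference([annotate.UNANNOTATED, annotate.UNCLUSTERED])
    abundances = {
        fam: table.loc[fam, "mean"] * config.rad_scale
        for fam in fams if table.loc[fam, "mean"] > 0
    }
    results: dict = {"rejection_log": reject_log}
    if len(abundances) >= 1:
        div = ecology.diversity(abundances)
        results["diversity"] = {"H": div.H, "E": div.E, "richness": div.richness}
        (out / "diversity.json").write_text(json.dumps(results["diversity"]))
        fits = ecology.select_model(abundances)
        summary = ecology.fit_summary(fits)
        summary.to_json(out / "radfit.json", orient="records")
        results["best_rad_model"] = fits[0].model
    if config.transcripts:
        transcripts = list(seqio.read_fasta(config.transcripts))
        reads = [r for p in pairs for r in p]
        est = genomesize.estimate_genome_size(
            reads, transcripts, ploidy=config.ploidy,
            min_aln_len=config.gs_min_aln_len,
            min_identity=config.gs_min_identity, trim_top=config.gs_trim_top,
        )
        results["genome_size"] = {
            "cval_bp": est.cval, "mean_cov": est.mean_cov,
            "n_reads": est.n, "read_len": est.l, "ploidy": est.P,
        }
        (out / "genome_size.json").write_text(json.dumps(results["genome_size"]))
    manifest = {
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "replicate_seeds": seeds,
        "n_input_pairs": len(raw_pairs),
        "n_filtered_pairs": len(pairs),
        "results": {k: v for k, v in results.items() if k != "rejection_log"},
        "rejection_log": reject_log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
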