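"""End-to-end orchestration of the four analysis stages from one config.

A :class:`RunConfig` (typically loaded from YAML) names the input files,
toggles stages, and carries every threshold. :func:`run_pipeline` validates
all stage parameters up front, then runs harmonize → overlap → prs → cpsm →
knownloci in order, writing per-stage TSVs and a JSON manifest (seed,
package and library versions, input checksums) into the output directory.
All per-stage randomness derives from the single run seed through spawned
substreams keyed by stage name, so toggling one stage never perturbs
another's draws.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cpsm as cpsm_mod
from . import knownloci as kl_mod
from . import overlap as ov_mod
from . import prs as prs_mod
from .simulate import load_cohort, load_panel
from .sumstats import align_alleles, read_sumstats, write_pair

logger = logging.getLogger(__name__)

STAGES = ("harmonize", "overlap", "prs", "cpsm", "knownloci")

# fixed offsets so each stage gets an independent substream of the run seed
_STAGE_STREAM = {name: i for i, name in enumerate(STAGES)}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed (< 2^31) from the run seed."""
    ss = np.random.SeedSequence([seed, _STAGE_STREAM[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Validated parameters for one pipeline run."""

    outdir: str
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    harmonize: dict = field(default_factory=lambda: {"drop_palindromic": True})
    overlap: dict = field(default_factory=lambda: {
        "r2_threshold": ov_mod.DEFAULT_R2_THRESHOLD,
        "cutoffs": list(ov_mod.DEFAULT_CUTOFFS),
        "n_perm": 1000,
        "flag_alpha": ov_mod.DEFAULT_FLAG_ALPHA,
        "order_by": "a",
    })
    prs: dict = field(default_factory=lambda: {"tiers": dict(prs_mod.DEFAULT_TIERS)})
    cpsm: dict = field(default_factory=lambda: {
        "window": cpsm_mod.DEFAULT_WINDOW,
        "step": cpsm_mod.DEFAULT_STEP,
        "min_snps": cpsm_mod.DEFAULT_MIN_SNPS,
        "n_perm": 1000,
        "percentile": cpsm_mod.DEFAULT_PERCENTILE,
        "merge_gap": cpsm_mod.DEFAULT_MERGE_GAP,
    })
    knownloci: dict = field(default_factory=lambda: {"family_alpha": 0.05})

    def validate(self) -> None:
        """Check every enabled stage's parameters before anything runs."""
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if not (0 < self.overlap["r2_threshold"] < 1):
            raise ValueError("overlap.r2_threshold must be in (0, 1)")
        if any(not (0 < c <= 1) for c in self.overlap["cutoffs"]):
            raise ValueError("overlap.cutoffs must lie in (0, 1]")
        if self.overlap["n_perm"] < 0:
            raise ValueError("overlap.n_perm must be >= 0")
        if any(not (0 < t <= 1) for t in self.prs["tiers"].values()):
            raise ValueError("prs.tiers must lie in (0, 1]")
        if not (self.cpsm["window"] >= self.cpsm["min_snps"] >= 2):
            raise ValueError("cpsm needs window >= min_snps >= 2")
        if not (0 < self.cpsm["percentile"] < 1):
            raise ValueError("cpsm.percentile must be in (0, 1)")
        if not (0 < self.knownloci["family_alpha"] < 1):
            raise ValueError("knownloci.family_alpha must be in (0, 1)")
        enabled = [s for s in STAGES if self.stages.get(s)]
        needs = {
            "harmonize": ["sumstats_a", "sumstats_b"],
            "overlap": ["panel_prefix"],
            "prs": ["sumstats_b", "cohort_prefix"],
            "knownloci": [],
            "cpsm": [],
        }
        if any(s in enabled for s in ("overlap", "cpsm")) and \
                "harmonize" not in enabled:
            needs["overlap"].append("pair")
            needs["cpsm"] = ["pair"]
        for stage in enabled:
            for key in needs.get(stage, []):
                if key not in self.inputs:
                    raise ValueError(f"stage '{stage}' needs input '{key}'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(outdir=raw.get("outdir", "crossgwas_out"))
        cfg.seed = int(raw.get("seed", 0))
        cfg.inputs = raw.get("inputs", {})
        for section in ("stages", "harmonize", "overlap", "prs", "cpsm", "knownloci"):
            getattr(cfg, section).update(raw.get(section, {}))
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, *, config_path=None) -> dict:
    """Run the enabled stages in order; return the manifest dictionary.

    A stage failure raises with a stage-tagged message; outputs of completed
    stages are preserved in ``config.outdir``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config_path is not None:
        (outdir / "config.yaml").write_bytes(Path(config_path).read_bytes())

    import scipy
    import statsmodels
    manifest: dict = {
        "seed": config.seed,
        "versions": {
            "crossgwas": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "inputs": {},
        "stages_run": [],
        "outputs": [],
    }
    for key, path in config.inputs.items():
        p = Path(path if not key.endswith("_prefix") else f"{path}.snps.tsv")
        if p.exists():
            manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(p)}
        else:
            manifest["inputs"][key] = {"path": str(path)}

    pair = None
    panel = None

    def _out(name: str) -> Path:
        p = outdir / name
        manifest["outputs"].append(str(p))
        return p

    for stage in STAGES:
        if not config.stages.get(stage):
            continue
        logger.info("stage %s: starting", stage)
        try:
            if stage == "harmonize":
                a = read_sumstats(config.inputs["sumstats_a"])
                b = read_sumstats(config.inputs["sumstats_b"])
                pair = align_alleles(
                    a, b,
                    drop_palindromic=config.harmonize["drop_palindromic"])
                write_pair(pair, _out("pair.tsv"), _out("pair.drops.tsv"))

            elif stage == "overlap":
                if pair is None:
                    from .sumstats import read_pair
                    pair = read_pair(config.inputs["pair"])
                panel = panel or load_panel(config.inputs["panel_prefix"])
                pruned = ov_mod.ld_prune(
                    pair, panel,
                    r2_threshold=config.overlap["r2_threshold"],
                    order_by=config.overlap.get("order_by", "a"))
                scan = ov_mod.overlap_scan(
                    pair, pruned, config.overlap["cutoffs"],
                    flag_alpha=config.overlap["flag_alpha"])
                if config.overlap["n_perm"] > 0:
                    perm = ov_mod.permute_overlap(
                        pair, pruned, config.overlap["cutoffs"],
                        config.overlap["n_perm"],
                        stage_seed(config.seed, "overlap"))
                    scan = scan.merge(perm[["cutoff", "perm_p"]], on="cutoff")
                conc = [
                    {"cutoff": c, **vars(ov_mod.direction_concordance(pair, pruned, c))}
                    for c in config.overlap["cutoffs"]
                ]
                scan = scan.merge(pd.DataFrame(conc), on="cutoff")
                scan.to_csv(_out("overlap.tsv"), sep="\t", index=False)
                pd.DataFrame({"snp_id": pruned.snp_ids}).to_csv(
                    _out("pruned_snps.tsv"), sep="\t", index=False)

            elif stage == "prs":
                source = read_sumstats(config.inputs["sumstats_b"])
                cohort = load_cohort(config.inputs["cohort_prefix"])
                tiers = prs_mod.run_tiers(source, cohort, config.prs["tiers"])
                tiers.to_csv(_out("prs.tsv"), sep="\t", index=False)

            elif stage == "cpsm":
                if pair is None:
                    from .sumstats import read_pair
                    pair = read_pair(config.inputs["pair"])
                profiles = cpsm_mod.transform_profiles(pair)
                ws = cpsm_mod.scan_windows(
                    profiles, window=config.cpsm["window"],
                    step=config.cpsm["step"], min_snps=config.cpsm["min_snps"])
                thr = cpsm_mod.permutation_threshold(
                    profiles, window=config.cpsm["window"],
                    step=config.cpsm["step"], min_snps=config.cpsm["min_snps"],
                    n_perm=config.cpsm["n_perm"],
                    percentile=config.cpsm["percentile"],
                    seed=stage_seed(config.seed, "cpsm"))
                regions = cpsm_mod.call_regions(
                    ws, thr, pair, merge_gap=config.cpsm["merge_gap"])
                rframe = cpsm_mod.regions_to_frame(regions)
                if "sumstats_mo" in config.inputs and "sumstats_ma" in config.inputs:
                    mo = read_sumstats(config.inputs["sumstats_mo"])
                    ma = read_sumstats(config.inputs["sumstats_ma"])
                    rframe, summary = cpsm_mod.annotate_subtypes(regions, mo, ma)
                    with open(_out("cpsm_subtypes.json"), "w") as fh:
                        json.dump(summary, fh, indent=2)
                rframe.to_csv(_out("cpsm_regions.tsv"), sep="\t", index=False)
                cpsm_mod.write_regions_bed(regions, _out("cpsm_regions.bed"))
                manifest["cpsm_threshold"] = thr

            elif stage == "knownloci":
                for direction, leads_key, other_key in (
                        ("a_to_b", "leads_a", "sumstats_b"),
                        ("b_to_a", "leads_b", "sumstats_a")):
                    if leads_key not in config.inputs:
                        continue
                    leads = kl_mod.read_leads(config.inputs[leads_key])
                    other = read_sumstats(config.inputs[other_key])
                    res = kl_mod.cross_query(
                        leads, other,
                        family_alpha=config.knownloci["family_alpha"])
                    res.table.to_csv(_out(f"knownloci_{direction}.tsv"),
                                     sep="\t", index=False)
                    if len(res.excluded):
                        res.excluded.to_csv(
                            _out(f"knownloci_{direction}_excluded.tsv"),
                            sep="\t", index=False)
        except Exception as exc:
            with open(outdir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2)
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        manifest["stages_run"].append(stage)
        logger.info("stage %s: done", stage)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
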