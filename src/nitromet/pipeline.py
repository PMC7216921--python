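"""End-to-end orchestration: simulate or load a family, extract the active
site, reconstruct ancestors, train and apply the metal-dependence classifier,
compute identity matrices and unique residues, and measure fixture pocket
volumes — with seeds fanned out per stage and a checksummed output manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .align import LabeledAlignment, parse_label_tsv
from .asr import AncestralReconstruction, ASRConfig
from .classify import (KNOWN_CLASSES, MetalDependenceModel, TrainConfig,
                       encode_ancestor, encode_extant, pca_separability)
from .identity import group_mean_identity, unique_residues
from .pocket import InclusionRegion, PocketConfig, pocket_volume
from .simulate import FamilySpec, generate_family, generate_pocket_fixture
from .structures import parse_structure
from .substitution import jtt

#: Stage indices for deriving per-stage seeds from the master seed.
STAGES = ("simulate", "active_site", "asr", "encode", "train", "classify",
          "identity", "pocket")


def stage_seed(master_seed: int, stage: str) -> int:
    return (int(master_seed) + STAGES.index(stage)) % (2 ** 31 - 1)


@dataclass
class RunConfig:
    """One of ``family_spec`` (simulate) or ``input_paths`` (load) drives the
    run; the master seed is fanned out to stages as seed + stage index."""

    seed: int = 0
    output_dir: str | Path | None = None
    family_spec: FamilySpec | None = None
    input_paths: dict[str, str] | None = None
    train: TrainConfig | None = None
    asr_samples: int = 100

    def __post_init__(self):
        if (self.family_spec is None) == (self.input_paths is None):
            raise ValueError(
                "exactly one of family_spec or input_paths must be given")
        if self.train is not None and not 0 < self.train.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")

    def to_jsonable(self) -> dict:
        out = {"seed": self.seed, "asr_samples": self.asr_samples,
               "input_paths": self.input_paths}
        if self.family_spec is not None:
            out["family_spec"] = asdict(self.family_spec)
        if self.train is not None:
            out["train"] = asdict(self.train)
        return out


def run_all(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run report."""
    report: dict = {"stages": {}}

    # ---- inputs -------------------------------------------------------------
    if config.family_spec is not None:
        spec = FamilySpec(**{**asdict(config.family_spec),
                             "seed": stage_seed(config.seed, "simulate")})
        alignment, truth, newick = generate_family(spec)
        site_columns = truth.site_columns
        positions = truth.active_site_positions
        report["stages"]["simulate"] = {
            "n_sequences": len(alignment),
            "alignment_length": alignment.n_columns,
            "clade_sizes": {c: len(m) for c, m in truth.clades.items()},
        }
    else:
        paths = config.input_paths
        try:
            alignment = LabeledAlignment.from_fasta(
                Path(paths["alignment"]).read_text(),
                labels=parse_label_tsv(Path(paths["labels"]).read_text()))
            newick = Path(paths["tree"]).read_text()
            positions = [int(x) for x in
                         Path(paths["positions"]).read_text().split()]
        except KeyError as exc:
            raise ValueError(f"stage inputs: missing input path {exc}") from exc
        site_columns = [p - 1 for p in positions]
        truth = None
        report["stages"]["load"] = {"n_sequences": len(alignment),
                                    "alignment_length": alignment.n_columns}

    model = jtt()

    # ---- active site --------------------------------------------------------
    active = alignment.take_columns(site_columns)
    report["stages"]["active_site"] = {"n_positions": len(site_columns),
                                       "positions": list(positions)}

    # ---- ancestral reconstruction ------------------------------------------
    asr = AncestralReconstruction(newick, alignment, model).fit()
    support = {}
    for node in asr.internal_nodes:
        full = asr.support_summary(node)
        site = asr.support_summary(node, site_columns)
        support[node] = {"full_mean": full[0], "full_sd": full[1],
                         "active_site_mean": site[0], "active_site_sd": site[1]}
    report["stages"]["asr"] = {
        "log_likelihood": asr.log_likelihood,
        "n_internal_nodes": len(asr.internal_nodes),
        "support": support,
    }

    # ---- encoding and training ---------------------------------------------
    features = encode_extant(active, model)
    labeled = [i for i, l in enumerate(alignment.labels)
               if l in KNOWN_CLASSES]
    X = features.data[labeled]
    y = [alignment.labels[i] for i in labeled]
    train_cfg = config.train or TrainConfig(seed=stage_seed(config.seed,
                                                            "train"))
    results = MetalDependenceModel(X, y).fit(train_cfg)
    report["stages"]["train"] = {
        "replicate_accuracies": results.replicate_accuracies,
        "deployed_C": results.model.C,
        "gamma": results.model.gamma,
        "class_weights": results.model.class_weights,
    }
    report["stages"]["pca"] = pca_separability(X, y)

    # ---- classification of unknowns and ancestors --------------------------
    unknown_rows = [i for i, l in enumerate(alignment.labels)
                    if l not in KNOWN_CLASSES]
    classified = {}
    if unknown_rows:
        res = results.classify(features.data[unknown_rows],
                               [alignment.names[i] for i in unknown_rows])
        classified.update({r.name: {"label": r.label, "support": r.distances}
                           for r in res})
    ancestor_nodes = (list(truth.deep_ancestors) + [truth.vnf_anf_ancestor]
                      if truth is not None else asr.internal_nodes)
    anc_class = {}
    for node in ancestor_nodes:
        row = encode_ancestor(asr, node, site_columns, positions)
        posterior = results.classify(row)[0]
        ml_seq = asr.ml_ancestor(node)
        ml_active = LabeledAlignment(
            [node], ["".join(ml_seq[c] for c in site_columns)], ["unknown"])
        ml_row = encode_extant(ml_active, model)
        ml = results.classify(ml_row)[0]
        anc_class[node] = {
            "posterior_label": posterior.label,
            "posterior_support": posterior.distances,
            "ml_label": ml.label,
            "ml_support": ml.distances,
        }
    report["stages"]["classify"] = {"unknown_leaves": classified,
                                    "ancestors": anc_class}

    # ---- identity and unique residues ---------------------------------------
    ident_full = group_mean_identity(alignment, scope="full")
    ident_site = group_mean_identity(alignment, site_columns, scope="active-site")
    table = unique_residues(active, positions=list(positions))
    report["stages"]["identity"] = {
        "full": json.loads(ident_full.group_means.to_json()),
        "active_site": json.loads(ident_site.group_means.to_json()),
        "unique_residue_counts": table.counts(),
        "unique_residues": [list(e) for e in table.entries],
    }

    # ---- pocket volumes (analytic fixtures on the synthetic path) ----------
    pocket_report = {}
    for kind, params, region in (
            ("sphere-shell", {"radius": 8.0},
             InclusionRegion.sphere((0, 0, 0), 8.0)),
            ("two-chamber", {"radius_large": 8.0, "radius_small": 6.0},
             None)):
        pdb_text, expected = generate_pocket_fixture(kind, params)
        structure = parse_structure(pdb_text)
        if region is None:
            region = InclusionRegion((((0.0, 0.0, 0.0), 8.0),
                                      ((18.0, 0.0, 0.0), 6.0)))
        result = pocket_volume(structure, region, PocketConfig())
        pocket_report[kind] = {"volume_A3": result.volume,
                               "analytic_A3": expected,
                               "stage_counts": result.stage_counts}
    report["stages"]["pocket"] = pocket_report

    report["config"] = config.to_jsonable()

    # ---- outputs -------------------------------------------------------------
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "alignment.fasta").write_text(alignment.to_fasta())
        (outdir / "labels.tsv").write_text(alignment.to_label_tsv())
        (outdir / "tree.nwk").write_text(newick.strip() + "\n")
        (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                       default=_jsonable))
        write_manifest(config, outdir)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(config: RunConfig, output_dir: str | Path) -> Path:
    """JSON manifest of inputs, seeds, config hash, and output checksums."""
    outdir = Path(output_dir)
    cfg_json = json.dumps(config.to_jsonable(), sort_keys=True,
                          default=_jsonable)
    manifest = {
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "outputs": {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                    if p.is_file() and p.name != "manifest.json"},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def verify_manifest(output_dir: str | Path) -> list[str]:
    """Recompute output checksums; returns the names that mismatch."""
    outdir = Path(output_dir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    bad = []
    for name, digest in manifest["outputs"].items():
        p = outdir / name
        if not p.is_file() or _sha256(p) != digest:
            bad.append(name)
    return bad
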