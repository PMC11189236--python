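"""Pipeline orchestration: staged execution, config, validation, manifest.

Stages run in dependency order — simulate -> contacts -> distances ->
features3d -> featurize -> evaluate — each reading and writing plain TSV
artifacts in the run directory so any stage can be re-run, diffed or
unit-tested in isolation.  A JSON manifest records the effective config,
seeds, and a checksum of every artifact; re-running with the same config
reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .association import CVConfig, DensityEfficiencyModel
from .contacts import balance, read_contacts, rebin, write_contacts
from .density import DensityFeatureSpec, feature_table, read_bin_features
from .distances import PathDistanceParams, all_pairs, build_graph, read_distances, write_distances
from .errors import DependencyError, ParameterError
from .simulate import SyntheticCrisprParams, SyntheticHiCParams, generate_contacts, generate_sites
from .targets import assemble, read_sites, write_sites

log = logging.getLogger("crispr3d")

STAGES = ("simulate", "contacts", "distances", "features3d", "featurize", "evaluate")

_SECTION_KEYS = {
    "simulate": {
        "n_bins", "resolution", "base_if", "decay_exponent", "tad_boundaries",
        "tad_enrichment", "coverage_noise_sd", "dropout_rate", "n_sites",
        "density_effect", "sequence_effect", "noise_sd", "planted_feature",
    },
    "contacts": {"path", "chrom", "resolution", "balance", "rebin_to"},
    "distances": {"p", "max_edges"},
    "features3d": {"distance_cutoffs", "radius_percentiles"},
    "featurize": {"with_3d", "window", "tracks", "folding_backend"},
    "evaluate": {"model", "k", "repeats", "feature_screen", "screen_scope", "quintile_q"},
}


@dataclass
class RunConfig:
    """Defaults-resolved configuration for a pipeline run.

    Every numeric knob of the method is surfaced with its working default:
    10 kb bins, d = 1/IF, p = 5 paths of <= 2 edges, Distance cutoffs
    {1000, 2500, 5000, 10000}, Radius percentiles {10, 15, 20, 25, 30},
    5-fold x 200-repeat CV, 20% efficiency quintiles.
    """

    out_dir: str = "run"
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    contacts: dict = field(default_factory=dict)
    distances: dict = field(default_factory=dict)
    features3d: dict = field(default_factory=dict)
    featurize: dict = field(default_factory=dict)
    evaluate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for section, allowed in _SECTION_KEYS.items():
            got = set(getattr(self, section))
            unknown = got - allowed
            if unknown:
                raise ParameterError(
                    f"unknown keys in config section {section!r}: {sorted(unknown)}"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage {stage!r} needs {path.name} (produced by stage {produced_by!r})"
        )
    return path


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages and return the run manifest."""
    bad = set(stages) - set(STAGES)
    if bad:
        raise ParameterError(f"unknown stages {sorted(bad)}")
    stages = tuple(s for s in STAGES if s in stages)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    log.info("effective config: %s", dataclasses.asdict(cfg))

    artifacts: dict[str, str] = {}

    def record(*paths: Path) -> None:
        for p in paths:
            artifacts[p.name] = _sha256(p)

    resolution = int(cfg.simulate.get("resolution", cfg.contacts.get("resolution", 10000)))
    chrom = str(cfg.contacts.get("chrom", "chrS"))

    if "simulate" in stages:
        sim = dict(cfg.simulate)
        hic = SyntheticHiCParams(
            n_bins=int(sim.get("n_bins", 200)),
            resolution=resolution,
            base_if=float(sim.get("base_if", 10.0)),
            decay_exponent=float(sim.get("decay_exponent", 1.0)),
            tad_boundaries=tuple(sim.get("tad_boundaries", ())),
            tad_enrichment=float(sim.get("tad_enrichment", 1.0)),
            coverage_noise_sd=float(sim.get("coverage_noise_sd", 0.2)),
            dropout_rate=float(sim.get("dropout_rate", 0.0)),
            seed=cfg.seed,
        )
        cr = SyntheticCrisprParams(
            n_sites=int(sim.get("n_sites", 300)),
            density_effect=float(sim.get("density_effect", -1.0)),
            sequence_effect=float(sim.get("sequence_effect", 0.5)),
            noise_sd=float(sim.get("noise_sd", 0.3)),
            seed=cfg.seed + 1,
        )
        m = generate_contacts(hic, chrom=chrom)
        write_contacts(m, out / "contacts.tsv")
        pd_ = all_pairs(build_graph(m), _path_params(cfg), chrom=chrom)
        spec = _density_spec(cfg)
        table = feature_table(pd_, spec, resolution=resolution)
        planted = str(cfg.simulate.get("planted_feature", table.feature_names[0]))
        sites = generate_sites(table, cr, density_feature=planted)
        write_sites(sites, out / "sites.tsv")
        record(out / "contacts.tsv", out / "sites.tsv")
        log.info("simulate: %d bins, %d sites, planted on %s", hic.n_bins, cr.n_sites, planted)

    if "contacts" in stages:
        src = Path(cfg.contacts.get("path", out / "contacts.tsv"))
        _require(src, "contacts", "simulate")
        m = read_contacts(src, resolution, chrom)
        method = str(cfg.contacts.get("balance", "none"))
        m = balance(m, method)
        if cfg.contacts.get("rebin_to"):
            m = rebin(m, int(cfg.contacts["rebin_to"]))
        write_contacts(m, out / "contacts_norm.tsv")
        record(out / "contacts_norm.tsv")

    if "distances" in stages:
        src = out / "contacts_norm.tsv"
        _require(src, "distances", "contacts")
        res = int(cfg.contacts.get("rebin_to") or resolution)
        m = read_contacts(src, res, chrom)
        pd_ = all_pairs(build_graph(m), _path_params(cfg), chrom=chrom)
        write_distances(pd_, out / "distances.tsv")
        record(out / "distances.tsv")

    if "features3d" in stages:
        src = _require(out / "distances.tsv", "features3d", "distances")
        pd_ = read_distances(src)
        res = int(cfg.contacts.get("rebin_to") or resolution)
        table = feature_table(pd_, _density_spec(cfg), resolution=res)
        table.to_tsv(out / "bin_features.tsv")
        record(out / "bin_features.tsv")

    if "featurize" in stages:
        sites_path = _require(out / "sites.tsv", "featurize", "simulate")
        feats_path = _require(out / "bin_features.tsv", "featurize", "features3d")
        sites = read_sites(sites_path)
        res = int(cfg.contacts.get("rebin_to") or resolution)
        table = read_bin_features(feats_path, resolution=res)
        with_3d = cfg.featurize.get("with_3d", table.feature_names[0])
        tracks = None
        if cfg.featurize.get("tracks"):
            from .targets import read_bedgraph

            tracks = {name: read_bedgraph(p) for name, p in cfg.featurize["tracks"].items()}
        fm = assemble(
            sites,
            table,
            include_3d=with_3d,
            tracks=tracks,
            window=int(cfg.featurize.get("window", 500)),
            folding_backend=str(cfg.featurize.get("folding_backend", "simple")),
        )
        fm.to_csv(out / "features.tsv", sep="\t")
        record(out / "features.tsv")

    if "evaluate" in stages:
        import pandas as pd

        src = _require(out / "features.tsv", "evaluate", "featurize")
        fm = pd.read_csv(src, sep="\t", index_col=0)
        with_3d = cfg.featurize.get("with_3d")
        if with_3d is None:  # last feature column before the response
            with_3d = fm.columns[-2]
        cv_cfg = CVConfig(
            k=int(cfg.evaluate.get("k", 5)),
            repeats=int(cfg.evaluate.get("repeats", 200)),
            model=str(cfg.evaluate.get("model", "lasso")),
            seed=cfg.seed,
            feature_screen=cfg.evaluate.get("feature_screen"),
            screen_scope=str(cfg.evaluate.get("screen_scope", "fold")),
        )
        results = DensityEfficiencyModel(fm, with_3d).fit(
            cv_cfg, quintile=float(cfg.evaluate.get("quintile_q", 0.2))
        )
        results.cv_report.to_tsv(out / "cv_report.tsv")
        results.cv_report.to_json(out / "cv_summary.json")
        (out / "summary.txt").write_text(results.summary() + "\n")
        record(out / "cv_report.tsv", out / "cv_summary.json", out / "summary.txt")
        log.info("evaluate:\n%s", results.summary())

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": list(stages),
        "config": dataclasses.asdict(cfg),
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _path_params(cfg: RunConfig) -> PathDistanceParams:
    return PathDistanceParams(
        p=int(cfg.distances.get("p", 5)), max_edges=int(cfg.distances.get("max_edges", 2))
    )


def _density_spec(cfg: RunConfig) -> DensityFeatureSpec:
    return DensityFeatureSpec(
        distance_cutoffs=tuple(cfg.features3d.get("distance_cutoffs", (1000, 2500, 5000, 10000))),
        radius_percentiles=tuple(cfg.features3d.get("radius_percentiles", (10, 15, 20, 25, 30))),
    )


def validate_inputs(paths: dict[str, str], resolution: int = 10000) -> list[dict]:
    """Report-only format checks.

    ``paths`` maps a file path to its declared format: "contacts", "sites"
    or "bedgraph".  Returns one verdict per file with the line number and
    message of the first violation (ok=True when clean).
    """
    report = []
    for path, fmt in paths.items():
        verdict = {"path": str(path), "format": fmt, "ok": True, "line": None, "message": ""}
        try:
            if fmt == "contacts":
                _validate_contacts(path, resolution)
            elif fmt == "sites":
                _validate_sites(path)
            elif fmt == "bedgraph":
                _validate_bedgraph(path)
            else:
                raise ParameterError(f"unknown format {fmt!r}")
        except _LineViolation as v:
            verdict.update(ok=False, line=v.line, message=v.message)
        except Exception as e:  # unreadable file, bad format name...
            verdict.update(ok=False, message=str(e))
        report.append(verdict)
    return report


class _LineViolation(Exception):
    def __init__(self, line: int, message: str):
        super().__init__(message)
        self.line, self.message = line, message


def _validate_contacts(path, resolution: int) -> None:
    with open(path) as fh:
        for no, ln in enumerate(fh, 1):
            if not ln.strip() or ln.startswith("#"):
                continue
            f = ln.rstrip("\n").split("\t")
            if len(f) != 3:
                raise _LineViolation(no, f"expected 3 columns, got {len(f)}")
            try:
                s1, s2, c = float(f[0]), float(f[1]), float(f[2])
            except ValueError:
                raise _LineViolation(no, "non-numeric field") from None
            if c < 0:
                raise _LineViolation(no, f"negative count {c}")
            for s in (s1, s2):
                if s < 0 or s % resolution:
                    raise _LineViolation(no, f"start {s:.0f} not a multiple of {resolution}")


def _validate_sites(path) -> None:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        need = ["chrom", "pos", "strand", "sequence", "efficiency"]
        if [c for c in need if c not in header]:
            raise _LineViolation(1, f"header must contain {need}")
        idx = {c: header.index(c) for c in need}
        for no, ln in enumerate(fh, 2):
            if not ln.strip():
                continue
            f = ln.rstrip("\n").split("\t")
            seq = f[idx["sequence"]].upper()
            if any(b not in "ACGT" for b in seq):
                raise _LineViolation(no, f"site {f[idx['chrom']]}:{f[idx['pos']]}: "
                                         f"non-ACGT base in sequence")
            if len(seq) < 21:
                raise _LineViolation(no, "sequence shorter than 21 nt")
            try:
                pos, eff = int(f[idx["pos"]]), float(f[idx["efficiency"]])
            except ValueError:
                raise _LineViolation(no, "non-numeric pos/efficiency") from None
            if pos < 0 or not 0 <= eff <= 1:
                raise _LineViolation(no, "pos must be >= 0 and efficiency in [0,1]")
            if f[idx["strand"]] not in "+-":
                raise _LineViolation(no, f"bad strand {f[idx['strand']]!r}")


def _validate_bedgraph(path) -> None:
    prev: dict[str, int] = {}
    with open(path) as fh:
        for no, ln in enumerate(fh, 1):
            if not ln.strip() or ln.startswith(("track", "#", "browser")):
                continue
            f = ln.split()
            if len(f) < 4:
                raise _LineViolation(no, "bedGraph needs 4 fields")
            try:
                start, end, _ = int(f[1]), int(f[2]), float(f[3])
            except ValueError:
                raise _LineViolation(no, "non-numeric bedGraph fields") from None
            if end <= start:
                raise _LineViolation(no, "interval end <= start")
            if start < prev.get(f[0], -1):
                raise _LineViolation(no, "intervals unsorted or overlapping")
            prev[f[0]] = end
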