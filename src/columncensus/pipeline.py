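"""Pipeline orchestration, artifacts, and connectivity cards.

Stages run in dependency order (compartments -> subclasses -> mtypes ->
connectivity -> selectivity -> cards), each writing CSV/JSON artifacts into
the output directory plus a manifest with the config hash, the seed, and a
checksum for every output file.  A full run with an unchanged config and
seed reproduces every artifact byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import compartments as comp
from . import connectivity as conn
from . import mtypes as mt
from . import selectivity as sel
from . import subclasses as sc
from . import synthetic
from .skeleton import COMPARTMENT_NAMES
from .tables import read_bundle, write_bundle

logger = logging.getLogger(__name__)

STAGES = ("compartments", "subclasses", "mtypes", "connectivity",
          "selectivity", "cards")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    bundle_dir: str | None = None     # input bundle (or generate one)
    generate: str | None = None       # spec factory: default/calibration/...
    seed: int = 0
    out_dir: str = "artifacts"
    n_consensus_runs: int = 50
    subsample: float = 0.95
    knn: int = 10
    resolution: float = 1.3
    k_range: tuple[int, int] = (2, 30)
    n_shuffles: int = 1000
    clump_threshold: float = 15.0
    apical_source: str = "model"      # "model" or "ground_truth"
    write_cards: bool = True

    @classmethod
    def from_toml(cls, path):
        import tomllib
        data = tomllib.loads(Path(path).read_text())
        if "k_range" in data:
            data["k_range"] = tuple(data["k_range"])
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


SPEC_FACTORIES = {
    "default": synthetic.default_column_spec,
    "calibration": synthetic.calibration_column_spec,
    "recovery": synthetic.recovery_column_spec,
    "motif": synthetic.motif_column_spec,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


class Pipeline:
    """Stateful runner holding in-memory stage products."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._load_bundle()
        self.processed = None         # cell_id -> ProcessedCell
        self.labeled_synapses = None
        self.subclass_features = None
        self.subclass_labels = None
        self.mtype_labels = None
        self.mtype_features = None
        self.budgets = None
        self.motif_labels = None
        self.si_table = None

    # -- input -------------------------------------------------------------

    def _load_bundle(self):
        cfg = self.config
        if cfg.generate is not None:
            factory = SPEC_FACTORIES.get(cfg.generate)
            if factory is None:
                raise PipelineError(f"unknown generator spec: {cfg.generate}")
            spec = factory(seed=cfg.seed)
            (self.cells, self.skeletons, self.synapses, self.geometry,
             self.ground_truth) = synthetic.generate_column(spec)
            bundle_dir = self.out / "bundle"
            write_bundle(bundle_dir, self.cells, self.skeletons, self.synapses,
                         self.geometry, self.ground_truth)
        elif cfg.bundle_dir is not None:
            (self.cells, self.skeletons, self.synapses,
             self.geometry) = read_bundle(cfg.bundle_dir)
            gt_path = Path(cfg.bundle_dir) / "ground_truth.json"
            self.ground_truth = (synthetic.GroundTruth.from_json(gt_path)
                                 if gt_path.exists() else None)
        else:
            raise PipelineError("config needs bundle_dir or generate")

    # -- stages ------------------------------------------------------------

    def run(self, only=None):
        stages = STAGES if only is None else STAGES[:STAGES.index(only) + 1]
        for stage in stages:
            if only is not None and stage != only and self._stage_done(stage):
                self._load_stage(stage)
                continue
            logger.info("running stage %s", stage)
            getattr(self, f"stage_{stage}")()
        self._write_manifest()
        return self.out

    def _stage_done(self, stage) -> bool:
        markers = {
            "compartments": "synapse_labels.csv",
            "subclasses": "subclasses.csv",
            "mtypes": "mtypes.csv",
            "connectivity": "budgets.csv",
            "selectivity": "si.csv",
            "cards": "cards",
        }
        return (self.out / markers[stage]).exists()

    def _load_stage(self, stage):
        if stage == "compartments":
            self._ensure_processed()
        elif stage == "subclasses":
            df = pd.read_csv(self.out / "subclasses.csv", index_col=0)
            self.subclass_labels = df["subclass"]
            self.subclass_features = df[sc.FEATURE_NAMES]
        elif stage == "mtypes":
            df = pd.read_csv(self.out / "mtypes.csv", index_col=0)
            self.mtype_labels = df["mtype"]
            self.mtype_features = pd.read_csv(
                self.out / "mtype_features.csv", index_col=0)
        elif stage == "connectivity":
            self.budgets = pd.read_csv(self.out / "budgets.csv", index_col=0)
            self.budgets.columns.name = None
            self.motif_labels = pd.read_csv(
                self.out / "motif_groups.csv", index_col=0)["motif_group"]
        elif stage == "selectivity":
            self.si_table = pd.read_csv(self.out / "si.csv")

    def _require(self, attr, stage):
        if getattr(self, attr) is None:
            raise PipelineError(
                f"missing prerequisite stage '{stage}' (run it first)")

    def _ensure_processed(self):
        if self.processed is not None:
            return
        cfg = self.config
        truth = self.ground_truth
        use_truth = cfg.apical_source == "ground_truth"
        if use_truth and truth is None:
            raise PipelineError("apical_source=ground_truth needs ground truth")
        processed = {}
        class_of = dict(zip(self.cells["cell_id"].astype(int),
                            self.cells["coarse_class"]))
        vol_of = dict(zip(self.cells["cell_id"].astype(int),
                          self.cells["nucleus_volume"]))
        # Optionally train the apical vertex model on planted labels.
        model = None
        if not use_truth and truth is not None:
            model = self._train_apical_model()
        syn = self.synapses
        by_post = syn.groupby("post_cell").groups
        by_pre = syn.groupby("pre_cell").groups
        for cid, skel in self.skeletons.items():
            cls = class_of[cid]
            inputs = syn.loc[by_post.get(cid, [])]["post_vertex"].to_numpy(dtype=np.int64)
            outputs = syn.loc[by_pre.get(cid, [])]["pre_vertex"].to_numpy(dtype=np.int64)
            kwargs = {}
            if cls == "excitatory":
                if use_truth:
                    kwargs["apical_roots"] = truth.apical_roots.get(cid, [])
                elif model is not None:
                    collapsed, _ = comp.collapse_soma(skel, vol_of[cid])
                    feats = comp.vertex_apical_features(collapsed, self.geometry)
                    kwargs["apical_probability"] = model.apical_probability(feats)
            processed[cid] = comp.process_cell(
                skel, vol_of[cid], cls, inputs, outputs, **kwargs)
        self.processed = processed

    def _train_apical_model(self):
        """Retrain the apical vertex model on planted apical subtrees."""
        truth = self.ground_truth
        X, y = [], []
        exc = self.cells[self.cells["coarse_class"] == "excitatory"]
        for cid in exc["cell_id"].astype(int):
            roots = truth.apical_roots.get(cid, [])
            skel = self.skeletons[cid]
            feats = comp.vertex_apical_features(skel, self.geometry)
            apical = np.zeros(skel.n_vertices, dtype=int)
            for r in roots:
                apical[skel.subtree_mask(int(r))] = 1
            dend = skel.dendrite_mask()
            dend[skel.root] = False
            X.append(feats[dend])
            y.append(apical[dend])
        model = comp.ApicalVertexModel(random_state=self.config.seed % (2**31))
        model.fit(np.vstack(X), np.concatenate(y))
        return model

    def stage_compartments(self):
        self._ensure_processed()
        self.labeled_synapses = comp.label_synapses(
            self.synapses, self.cells, self.processed)
        out = self.labeled_synapses[["synapse_id", "compartment", "post_class"]]
        out.to_csv(self.out / "synapse_labels.csv", index=False)
        rows = []
        for cid, pc in sorted(self.processed.items()):
            skel = pc.skeleton
            for v in range(skel.n_vertices):
                rows.append((cid, v, int(skel.vertex_label[v]),
                             COMPARTMENT_NAMES[int(skel.compartment[v])]))
        pd.DataFrame(rows, columns=["cell_id", "vertex", "label", "compartment"]
                     ).to_csv(self.out / "vertex_labels.csv", index=False)

    def _ensure_labeled(self):
        if self.labeled_synapses is None:
            self._ensure_processed()
            self.labeled_synapses = comp.label_synapses(
                self.synapses, self.cells, self.processed)

    def stage_subclasses(self):
        self._ensure_labeled()
        feats = sc.targeting_feature_table(
            self.labeled_synapses, self.cells, self.skeletons,
            clump_threshold=self.config.clump_threshold)
        expert = self.cells.set_index("cell_id")["expert_subclass"]
        _, labels = sc.fit_and_assign_subclasses(feats, expert)
        self.subclass_features = feats
        self.subclass_labels = labels
        out = feats.copy()
        out["subclass"] = labels
        out.index.name = "cell_id"
        out.to_csv(self.out / "subclasses.csv")
        matrix = sc.subclass_connectivity_matrix(self.labeled_synapses, labels)
        matrix.to_csv(self.out / "subclass_connectivity.csv")
        inhtc, fractions = sc.split_inhtc(self.labeled_synapses, labels)
        _write_json(self.out / "inhtc_subtypes.json",
                    {str(k): v for k, v in inhtc.items()})

    def stage_mtypes(self):
        self._ensure_labeled()
        cfg = self.config
        fm, components = mt.extract_mtype_features(
            self.cells, self.processed, self.synapses, self.geometry,
            random_state=cfg.seed % (2**31))
        engine = mt.consensus_cluster(
            fm, n_runs=cfg.n_consensus_runs, subsample=cfg.subsample,
            knn=cfg.knn, resolution=cfg.resolution, k_range=cfg.k_range,
            seed=cfg.seed % (2**31))
        raw = pd.Series(engine.labels_, index=fm.index)
        expert = self.cells.set_index("cell_id")["expert_mtype"]
        depths = pd.Series(
            self.geometry.depth(
                self.cells.set_index("cell_id")[["soma_x", "soma_y", "soma_z"]]
                .to_numpy()),
            index=self.cells["cell_id"].astype(int))
        named = mt.name_and_order_clusters(raw, expert, depths)
        self.mtype_labels = named.rename("mtype")
        self.mtype_features = fm
        df = pd.DataFrame({"mtype": named, "cluster": raw})
        df.index.name = "cell_id"
        df.to_csv(self.out / "mtypes.csv")
        fm.rename_axis("cell_id").to_csv(self.out / "mtype_features.csv")
        np.save(self.out / "co_clustering.npy", engine.co_clustering_)
        _write_json(self.out / "consensus_traces.json",
                    {"n_clusters": engine.n_clusters_,
                     "davies_bouldin": {str(k): v for k, v in engine.db_trace_.items()},
                     "silhouette": {str(k): v for k, v in engine.silhouette_trace_.items()}})
        _write_json(self.out / "components.json",
                    {k: np.asarray(v).tolist() for k, v in components.items()})
        importance = mt.mtype_feature_importance(
            fm, self.mtype_labels, random_state=cfg.seed % (2**31))
        importance.rename_axis("mtype").to_csv(self.out / "mtype_importance.csv")

    def stage_connectivity(self):
        self._require("subclass_labels", "subclasses")
        self._require("mtype_labels", "mtypes")
        self._ensure_labeled()
        cfg = self.config
        mat, per_post, per_pre = conn.net_input_summary(
            self.labeled_synapses, self.subclass_labels, self.mtype_labels)
        mat.rename_axis("subclass").to_csv(self.out / "net_input.csv")
        per_post.rename_axis("cell_id").to_csv(self.out / "net_input_per_cell.csv")
        dens = conn.density_table(self.labeled_synapses, self.subclass_labels,
                                  self.mtype_labels)
        dens.rename_axis("cell_id").to_csv(self.out / "density.csv")
        budgets = conn.budget_table(self.labeled_synapses, self.subclass_labels,
                                    self.mtype_labels)
        self.budgets = budgets
        budgets.rename_axis("cell_id").to_csv(self.out / "budgets.csv")
        depths = pd.Series(
            self.geometry.depth(
                self.cells.set_index("cell_id")[["soma_x", "soma_y", "soma_z"]]
                .to_numpy()),
            index=self.cells["cell_id"].astype(int))
        mtype_depths = depths.groupby(self.mtype_labels).median()
        labels, group_output, _ = conn.motif_groups(
            budgets, mtype_depths, n_runs=cfg.n_consensus_runs,
            subsample=cfg.subsample, knn=min(cfg.knn, max(2, len(budgets) // 4)),
            resolution=cfg.resolution, k_range=cfg.k_range,
            seed=(cfg.seed + 1) % (2**31))
        self.motif_labels = labels
        labels.rename_axis("cell_id").to_frame().to_csv(self.out / "motif_groups.csv")
        group_output.rename_axis("motif_group").to_csv(self.out / "group_output.csv")
        frac = conn.input_fraction_matrix(self.labeled_synapses, labels,
                                          self.mtype_labels)
        frac.rename_axis("motif_group").to_csv(self.out / "input_fractions.csv")

    def stage_selectivity(self):
        self._ensure_labeled()
        self._require("mtype_labels", "mtypes")
        cfg = self.config
        baseline = sel.build_baseline(self.labeled_synapses, self.cells,
                                      self.mtype_labels, self.geometry)
        si = sel.selectivity_table(self.labeled_synapses, self.cells, baseline,
                                   self.geometry, self.mtype_labels,
                                   n_shuffles=cfg.n_shuffles,
                                   seed=cfg.seed % (2**31))
        self.si_table = si
        si.to_csv(self.out / "si.csv", index=False)
        if self.motif_labels is not None and len(si):
            med, all_ns = sel.group_selectivity_matrix(si, self.motif_labels)
            med.rename_axis("motif_group").to_csv(self.out / "group_si.csv")

    def stage_cards(self):
        if not self.config.write_cards:
            return
        self._ensure_labeled()
        self._require("subclass_labels", "subclasses")
        self._require("mtype_labels", "mtypes")
        self._require("si_table", "selectivity")
        cards_dir = self.out / "cards"
        cards_dir.mkdir(exist_ok=True)
        for cid in sorted(self.subclass_labels.index):
            card = self.connectivity_card(int(cid))
            _write_json(cards_dir / f"{cid}.json", card)

    # -- cards --------------------------------------------------------------

    def connectivity_card(self, cell_id: int) -> dict:
        """Assemble one interneuron's connectivity card from artifacts."""
        pc = self.processed[cell_id]
        skel = pc.skeleton
        depths = self.geometry.depth(skel.positions)
        syn = self.labeled_synapses
        out = syn[(syn["pre_cell"] == cell_id) & (syn["compartment"] != "none")
                  & (syn["post_cell"] != cell_id)]
        comp_hist = out["compartment"].value_counts(normalize=True).to_dict()
        exc = out[out["post_class"] == "excitatory"].copy()
        exc["mtype"] = exc["post_cell"].map(self.mtype_labels)
        by_mtype = {}
        if len(exc):
            for mtype, grp in exc.groupby("mtype", observed=True):
                by_mtype[str(mtype)] = {
                    "fraction": len(grp) / len(exc),
                    "compartments": grp["compartment"].value_counts(normalize=True).to_dict(),
                }
        si_rows = self.si_table[self.si_table["pre_cell"] == cell_id] if self.si_table is not None else []
        si = {}
        if len(si_rows):
            for _, row in si_rows.iterrows():
                si[str(row["target_class"])] = {
                    "si": None if not np.isfinite(row["si"]) else float(row["si"]),
                    "significant": bool(row["significant"]),
                }
        try:
            pref = sel.compartment_preference(
                cell_id, self.labeled_synapses, self.cells, self.geometry,
                self.mtype_labels, n_shuffles=self.config.n_shuffles,
                seed=(self.config.seed + cell_id) % (2**31))
            pref_vec = {str(k): float(v) for k, v in pref["si"].items()
                        if np.isfinite(v)}
        except sel.SelectivityError:
            pref_vec = {}
        return {
            "cell_id": cell_id,
            "subclass": str(self.subclass_labels.get(cell_id)),
            "morphology": {
                "cable_length_um": skel.total_cable_length(skel.dendrite_mask()),
                "soma_depth_um": float(depths[skel.root]),
                "depth_extent_um": [float(depths.min()), float(depths.max())],
            },
            "compartment_output_fractions": {str(k): float(v)
                                             for k, v in comp_hist.items()},
            "mtype_output": by_mtype,
            "selectivity": si,
            "compartment_preference": pref_vec,
        }

    # -- manifest ------------------------------------------------------------

    def _write_manifest(self):
        files = {}
        for p in sorted(self.out.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                files[str(p.relative_to(self.out))] = _sha256(p)
        _write_json(self.out / "manifest.json", {
            "config_digest": self.config.digest(),
            "seed": self.config.seed,
            "stages": list(STAGES),
            "files": files,
        })


def run_pipeline(config: PipelineConfig, only=None) -> Path:
    """Run the pipeline (all stages, or up to/just ``only``)."""
    return Pipeline(config).run(only=only)
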