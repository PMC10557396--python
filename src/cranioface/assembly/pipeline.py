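"""End-to-end coarse-to-fine facial approximation.

Training learns, from a cohort of corresponded skull/face meshes in a
common Frankfort frame: the average skull (whose vertex normals become the
fixed depth-measurement directions), per-point soft-tissue depth
statistics, nose/mouth hard-to-soft regressions, and the facial SSM.

Approximation runs: Frankfort alignment -> hybrid registration of the
average skull onto the dry skull -> semilandmark projection -> depth-based
envelope -> organ prediction -> boundary placement -> SSM fitting ->
Laplacian refinement. All intermediates are kept for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..craniofacial_model.fstd import (
    FSTDStatistics,
    fstd_statistics,
    impute_missing_depths,
    measure_fstd,
)
from ..craniofacial_model.regression import (
    RegressionModel,
    choose_eta,
    fit_organ_regression,
    predict_organ,
    project_to_shape_space,
)
from ..meshkit.frankfort import FrankfortError, frankfort_frame
from ..meshkit.landmarks import ComponentLabels, Configuration, LandmarkSet
from ..meshkit.mesh import TriangleMesh, compute_vertex_normals
from ..morphometrics.gpa import centroid_size, gpa
from ..morphometrics.pca import pca_shapes
from ..registration.nicp import hybrid_register
from ..registration.project import project_semilandmarks
from ..registration.tps import tps_fit
from .laplacian import RefinedFace, laplacian_refine
from .placement import PlacementResult, place_component
from .ssm import FaceSSM, FrameTransfer, build_ssm, fit_ssm, transform_to_ssm_frame


class PipelineError(RuntimeError):
    """Stage failure; carries the failing stage's name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineSettings:
    cumulative_threshold: float = 0.95
    organ_eta: float | None = None          # None -> LOOCV grid per organ
    ssm_lambda: float | None = None         # None -> 1e-3 * sqrt(lead eigval)
    anchor_weight: float = 1.0
    # stiffer than the generic registration default: template/specimen shape
    # differences here are smooth and landmark-anchored, and gentler NICP
    # preserves the TPS correspondence quality
    stiffness_schedule: tuple[float, ...] = (100.0, 50.0, 20.0)
    nicp_max_iter: int = 6
    max_depth: float = 60.0
    tps_control_points: int = 250
    boundary_samples: int = 100


ORGAN_HARD_LABEL = {"nose": "nasal", "mouth": "oral"}


@dataclass
class TrainedModel:
    """Everything learned from a training cohort, in the Frankfort frame."""

    template_faces: np.ndarray
    average_skull: TriangleMesh             # carries the measurement normals
    average_face: TriangleMesh
    directions: np.ndarray                  # (k, 3) average-skull vertex normals
    skull_labels: ComponentLabels
    face_labels: ComponentLabels
    fstd: FSTDStatistics
    mean_depths: np.ndarray                 # imputed per-point mean depths
    skull_landmarks: LandmarkSet            # cohort-average skull landmarks
    organ_models: dict[str, RegressionModel]
    organ_indices: dict[str, np.ndarray]    # template indices, landmarks first
    organ_faces: dict[str, np.ndarray]      # patch topology in config order
    ssm: FaceSSM
    settings: PipelineSettings

    @property
    def k(self) -> int:
        return self.average_skull.n_vertices


def _frankfort_of(landmarks: LandmarkSet):
    for name in ("Lp", "Rp", "Lo", "G"):
        if name not in landmarks:
            raise PipelineError("frankfort", f"missing landmark {name!r}")
    try:
        return frankfort_frame(
            landmarks["Lp"], landmarks["Rp"], landmarks["Lo"], landmarks["G"]
        )
    except FrankfortError as exc:
        raise PipelineError("frankfort", str(exc)) from exc


def _patch_faces(template_faces: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Template faces restricted to a patch, remapped to config order."""
    pos = {int(v): j for j, v in enumerate(order)}
    keep = np.array([all(int(v) in pos for v in f) for f in template_faces])
    return np.array(
        [[pos[int(v)] for v in f] for f in template_faces[keep]], dtype=np.int64
    )


def train_pipeline(
    skulls: list[TriangleMesh],
    faces: list[TriangleMesh],
    skull_landmarks: list[LandmarkSet],
    skull_labels: ComponentLabels,
    face_labels: ComponentLabels,
    organ_landmark_indices: dict[str, np.ndarray],
    settings: PipelineSettings | None = None,
) -> TrainedModel:
    """Learn the craniofacial model from corresponded training specimens.

    All meshes must share the template topology (vertex-wise
    correspondence); each specimen is first carried into its own Frankfort
    frame via its skull landmarks.
    """
    settings = settings or PipelineSettings()
    n = len(skulls)
    if n < 3:
        raise PipelineError("train", "need at least 3 training specimens")
    template_faces = skulls[0].faces.copy()
    sk_al, fc_al, lm_al = [], [], []
    for i in range(n):
        xf = _frankfort_of(skull_landmarks[i])
        sk_al.append(xf.apply(skulls[i].vertices))
        fc_al.append(xf.apply(faces[i].vertices))
        lm_al.append(
            LandmarkSet(skull_landmarks[i].names, xf.apply(skull_landmarks[i].points))
        )
    avg_skull_pts = np.mean(sk_al, axis=0)
    avg_face_pts = np.mean(fc_al, axis=0)
    average_skull = compute_vertex_normals(TriangleMesh(avg_skull_pts, template_faces))
    average_face = TriangleMesh(avg_face_pts, template_faces.copy())
    directions = average_skull.normals
    common_names = lm_al[0].names
    avg_lm = LandmarkSet(
        common_names, np.mean([lm.subset(common_names).points for lm in lm_al], axis=0)
    )

    fields = [
        measure_fstd(sk_al[i], directions, TriangleMesh(fc_al[i], template_faces),
                     max_depth=settings.max_depth)
        for i in range(n)
    ]
    stats = fstd_statistics(fields)
    mean_depths = impute_missing_depths(avg_skull_pts, stats.point_mean)

    organ_models: dict[str, RegressionModel] = {}
    organ_indices: dict[str, np.ndarray] = {}
    organ_faces: dict[str, np.ndarray] = {}
    for organ in ("nose", "mouth"):
        hard_mask = skull_labels.mask(ORGAN_HARD_LABEL[organ])
        soft_mask = face_labels.mask(organ)
        lead = np.asarray(organ_landmark_indices[organ], dtype=np.int64)
        patch = np.flatnonzero(soft_mask)
        order = np.concatenate([lead, np.setdiff1d(patch, lead)])
        if not np.array_equal(np.flatnonzero(hard_mask), np.sort(patch)):
            # hard and soft patches may differ; use each side's own indices
            hard_patch = np.flatnonzero(hard_mask)
            hard_order = np.concatenate(
                [lead[np.isin(lead, hard_patch)],
                 np.setdiff1d(hard_patch, lead)]
            )
        else:
            hard_order = order
        organ_indices[organ] = order
        organ_faces[organ] = _patch_faces(template_faces, order)
        hard_cfgs = [s[hard_order] for s in sk_al]
        soft_cfgs = [f[order] for f in fc_al]
        g_hard = gpa(hard_cfgs, with_scaling=True)
        g_soft = gpa(soft_cfgs, with_scaling=True)
        hs = pca_shapes(g_hard, settings.cumulative_threshold)
        ss = pca_shapes(g_soft, settings.cumulative_threshold)
        H = np.stack([project_to_shape_space(hs, x) for x in hard_cfgs])
        S = np.stack([project_to_shape_space(ss, x) for x in soft_cfgs])
        eta = settings.organ_eta
        if eta is None:
            eta = choose_eta(H, S)
        organ_models[organ] = fit_organ_regression(H, S, hs, ss, eta)
        organ_models[organ].hard_indices = hard_order  # type: ignore[attr-defined]

    ssm = build_ssm(
        [f for f in fc_al], settings.cumulative_threshold, faces=template_faces
    )
    return TrainedModel(
        template_faces=template_faces,
        average_skull=average_skull,
        average_face=average_face,
        directions=directions,
        skull_labels=skull_labels,
        face_labels=face_labels,
        fstd=stats,
        mean_depths=mean_depths,
        skull_landmarks=avg_lm,
        organ_models=organ_models,
        organ_indices=organ_indices,
        organ_faces=organ_faces,
        ssm=ssm,
        settings=settings,
    )


@dataclass
class ApproximationResult:
    refined: RefinedFace
    coarse_points: np.ndarray               # (k, 3) coarse face, skull frame
    final_mesh: TriangleMesh                # refined face back in skull frame
    stages: dict = field(default_factory=dict)


def approximate_face(
    dry_skull: TriangleMesh,
    dry_landmarks: LandmarkSet,
    trained: TrainedModel,
    settings: PipelineSettings | None = None,
) -> ApproximationResult:
    """Generate a refined approximated face for a dry skull."""
    settings = settings or trained.settings
    stages: dict = {}
    k = trained.k
    tf = trained.template_faces

    # 1. Frankfort alignment of the dry skull
    xf_frank = _frankfort_of(dry_landmarks)
    skull = TriangleMesh(xf_frank.apply(dry_skull.vertices), dry_skull.faces.copy())
    lm = LandmarkSet(dry_landmarks.names, xf_frank.apply(dry_landmarks.points))
    stages["frankfort"] = xf_frank

    # 2. hybrid registration: average skull -> dry skull
    common = [n for n in trained.skull_landmarks.names if n in lm]
    if len(common) < 4:
        raise PipelineError("register", "fewer than 4 shared skull landmarks")
    try:
        hyb = hybrid_register(
            trained.average_skull,
            skull,
            trained.skull_landmarks.subset(common).points,
            lm.subset(common).points,
            stiffness_schedule=settings.stiffness_schedule,
            max_iter=settings.nicp_max_iter,
        )
    except Exception as exc:
        raise PipelineError("register", str(exc)) from exc
    stages["registration"] = hyb

    # 3. project semilandmarks onto the dry skull
    dry_config = project_semilandmarks(hyb.deformed.vertices, skull).points
    stages["dry_config"] = dry_config

    # 4. depth-based facial envelope over the bony envelope
    env_idx = np.flatnonzero(trained.skull_labels.mask("envelope"))
    env_pts = dry_config[env_idx] + (
        trained.directions[env_idx] * trained.mean_depths[env_idx, None]
    )
    env_faces = _patch_faces(tf, env_idx)
    envelope_mesh = TriangleMesh(env_pts, env_faces)
    stages["envelope"] = envelope_mesh

    # 5. deformed average face: transfer the skull deformation via TPS
    step = max(1, k // settings.tps_control_points)
    ctrl = np.arange(0, k, step)
    warp = tps_fit(
        trained.average_skull.vertices[ctrl], dry_config[ctrl],
        regularization=1e-6,
    )
    def_avg_face = TriangleMesh(warp.apply(trained.average_face.vertices), tf.copy())
    stages["deformed_average_face"] = def_avg_face

    # 6. organ prediction and boundary placement
    coarse = np.full((k, 3), np.nan)
    coarse[env_idx] = env_pts
    placements: dict[str, PlacementResult] = {}
    for organ in ("nose", "mouth"):
        model = trained.organ_models[organ]
        hard_order = getattr(model, "hard_indices")
        hard_cfg = Configuration(dry_config[hard_order])
        pred = predict_organ(model, hard_cfg)
        order = trained.organ_indices[organ]
        # metric scale: match the deformed-average component's centroid size
        target_cs = centroid_size(def_avg_face.vertices[order])
        pred_cs = centroid_size(pred.points)
        pred_pts = pred.points * (target_cs / pred_cs)
        pred_mesh = TriangleMesh(pred_pts, trained.organ_faces[organ])
        try:
            placement = place_component(
                pred_mesh, def_avg_face, trained.face_labels, organ,
                m=settings.boundary_samples,
            )
        except Exception as exc:
            raise PipelineError(f"place_{organ}", str(exc)) from exc
        placements[organ] = placement
        coarse[order] = placement.placed_points
    stages["placements"] = placements
    if np.isnan(coarse).any():
        missing = np.flatnonzero(np.isnan(coarse).any(axis=1))
        coarse[missing] = def_avg_face.vertices[missing]
    stages["coarse_points"] = coarse.copy()

    # 7. carry the coarse face into the SSM frame via ray correspondences
    try:
        transfer: FrameTransfer = transform_to_ssm_frame(
            coarse, envelope_mesh, def_avg_face, trained.ssm,
            dry_config, trained.directions, max_depth=settings.max_depth,
        )
    except Exception as exc:
        raise PipelineError("ssm_frame", str(exc)) from exc
    stages["frame_transfer"] = transfer

    # 8. SSM fitting (fills eyes/ears/missing geometry)
    beta, fitted_pts = fit_ssm(trained.ssm, transfer.correspondences,
                               lam=settings.ssm_lambda)
    fitted_mesh = TriangleMesh(fitted_pts, tf.copy())
    stages["ssm_beta"] = beta

    # 9. Laplacian refinement toward the coarse soft tissues
    coarse_ssm = transfer.transform.apply(coarse)
    anchors: dict[int, np.ndarray] = {}
    for _, i in transfer.correspondences:
        anchors[int(i)] = coarse_ssm[i]
    for organ in ("nose", "mouth"):
        for i in trained.organ_indices[organ]:
            anchors[int(i)] = coarse_ssm[i]
    refined = laplacian_refine(fitted_mesh, anchors,
                               anchor_weight=settings.anchor_weight)
    # 10. back into the dry-skull (Frankfort) frame
    inv = transfer.transform.inverse()
    final = TriangleMesh(inv.apply(refined.mesh.vertices), tf.copy())
    return ApproximationResult(
        refined=refined, coarse_points=coarse, final_mesh=final, stages=stages
    )
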