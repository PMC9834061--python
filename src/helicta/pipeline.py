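"""The iterative filament-analysis pipeline.

Runs the full 2D-projected helical reconstruction loop on segmented
filaments: orient and center segments, project them, align the projections
against azimuthal views of a reference (a featureless cylinder at first),
back-project into 3D, refine the helical rise/twist, symmetrize, and feed
the symmetrized map back in as the next reference.  Three iterations by
default; the last one adds 2D classification with automated class selection
before the final reconstruction.  Filament polarity is voted on as a
diagnostic but never applied to the reconstruction.
"""

from __future__ import annotations

import warnings

import numpy as np

from .config import RunConfig, RunRecord
from .helical import (
    AlignSearch,
    ProjectionStack,
    ReconstructionResult,
    align_2d,
    align_2d_coherent,
    classify_2d,
    compute_fsc,
    project_segments,
    reconstruct_3d,
    refine_helical_params,
    segment_wedge_masks,
    select_classes,
    symmetrize_helix,
    vote_polarity,
)
from .segment import cylinder_reference, prepare_segments
from .simulate import AcquisitionGeometry, HelicalParams
from .tables import FilamentTrace
from .volume import Volume


class PipelineStageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and iteration."""

    def __init__(self, stage: str, iteration: int, cause: Exception):
        super().__init__(f"stage '{stage}' failed in iteration {iteration}: {cause}")
        self.stage = stage
        self.iteration = iteration


def run_filament_pipeline(
    config: RunConfig,
    tomograms: list[Volume],
    traces: list[FilamentTrace],
    initial_reference: Volume | None = None,
    helical_prior: HelicalParams | None = None,
    geometry: AcquisitionGeometry | None = None,
    search: AlignSearch | None = None,
    slab_fraction: float = 1.0 / 3.0,
    n_classes: int = 8,
    class_keep_fraction: float = 0.7,
    cylinder_radius: float = 40.0,
) -> ReconstructionResult:
    """Execute the full iterative helical reconstruction.

    Parameters
    ----------
    config:
        Controls the intersegment distance, box size, reference low-pass,
        number of iterations and the RNG seed.
    tomograms, traces:
        Input volumes (indexed by ``source_volume_id``) and picked filament
        centerlines.
    initial_reference:
        Seed reference for the first alignment round; a featureless cylinder
        when omitted (an actin-like map, low-pass filtered, is the realistic
        alternative).
    helical_prior:
        Center of the rise/twist search; canonical F-actin values
        (27.5 A, -166.7 deg) by default, matching the use of an actin
        reference to seed the analysis.
    geometry:
        When given, per-segment missing-wedge footprints are used for
        wedge-masked alignment scores.

    Returns a :class:`ReconstructionResult` whose extras carry the class
    averages, polarity votes, number of iterations and the run record.
    """
    record = RunRecord()
    record.log("config", **{k: getattr(config, k) for k in (
        "pixel_size_unbinned", "binning", "lowpass_reference",
        "intersegment_distance", "n_iterations", "rng_seed", "box_size")})
    if not traces:
        raise ValueError("no segments: the pipeline needs at least one filament trace")
    if helical_prior is None:
        helical_prior = HelicalParams(27.5, -166.7)
    if search is None:
        search = AlignSearch()
    rng = np.random.default_rng(config.rng_seed)

    def _stage(name, iteration, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise PipelineStageError(name, iteration, exc) from exc

    subs, table = _stage(
        "segment", 0, prepare_segments,
        tomograms, traces, config.intersegment_distance, config.box_size,
        cylinder_radius,
    )
    if not subs:
        raise PipelineStageError("segment", 0, ValueError("no segments survived extraction"))
    record.log("segment", n_segments=len(subs), spacing=config.intersegment_distance)

    stack = _stage("project", 0, project_segments, subs, table.df, slab_fraction)
    # seed azimuths uniformly at random (the first reference is azimuthally
    # featureless, so rot priors carry no information anyway)
    stack.table["rot"] = rng.uniform(0.0, 360.0, size=len(stack))

    px = stack.pixel_size
    if initial_reference is None:
        # seed with an F-actin-like helical model built from the prior (the
        # synthetic analogue of a published actin map); it is low-pass
        # filtered at every alignment round.  A featureless cylinder cannot
        # seed the loop: it carries no azimuthal information.
        from .simulate import make_filament_reference

        reference = make_filament_reference(config.box_size, px, helical_prior)
    else:
        reference = initial_reference
    wedge_masks = None
    if geometry is not None:
        wedge_masks = segment_wedge_masks(
            stack.table, geometry, stack.images.shape[1:], px
        )

    prior = helical_prior
    refined = prior
    diag = None
    class_result = None
    recon = None
    kept = np.ones(len(stack), bool)
    for it in range(1, config.n_iterations + 1):
        stack = _stage(
            "align_2d", it, align_2d_coherent,
            stack, reference, prior, search,
            lowpass_resolution=config.lowpass_reference,
            wedge_masks=wedge_masks,
        )
        work = stack
        if it == config.n_iterations and n_classes > 1 and len(stack) >= n_classes:
            class_result = _stage(
                "classify_2d", it, classify_2d, stack, n_classes,
                seed=int(rng.integers(2**31)),
            )
            kept = select_classes(class_result, class_keep_fraction)
            work = stack.select(kept)
            record.log(
                "classify_2d", iteration=it, k=n_classes,
                populations=class_result.populations, kept=int(kept.sum()),
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            recon = _stage("reconstruct_3d", it, reconstruct_3d, work, config.box_size)
        refined, diag = _stage("refine_helical_params", it, refine_helical_params, recon, prior)
        reference = _stage("symmetrize", it, symmetrize_helix, recon, refined)
        record.log(
            "iteration", iteration=it, rise=refined.rise, twist=refined.twist,
            n_images=len(work),
        )
        # the search prior stays anchored on the initial (actin-like) values:
        # re-centering it on each iteration's estimate lets small systematic
        # errors compound through the filament-coherent azimuth assignment,
        # while the anchored window always contains both prior and estimate

    votes, _ = vote_polarity(stack.table) if "flipped" in stack.table else (None, None)

    # half-set split by filament (never by segment) for the FSC
    final_stack = stack.select(kept)
    fil = final_stack.table["filament_id"].to_numpy()
    uniq = np.unique(fil)
    half_a_ids = set(uniq[::2])
    in_a = np.array([f in half_a_ids for f in fil])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if in_a.any() and (~in_a).any():
            map_a = symmetrize_helix(
                reconstruct_3d(final_stack.select(in_a), config.box_size), refined
            )
            map_b = symmetrize_helix(
                reconstruct_3d(final_stack.select(~in_a), config.box_size), refined
            )
            fsc, resolution = compute_fsc(map_a, map_b)
        else:
            fsc = np.zeros((0, 2))
            resolution = 2.0 * px
    record.log("fsc", resolution=resolution, n_half_a=int(in_a.sum()))

    return ReconstructionResult(
        map=reference,
        refined=refined,
        fsc=fsc,
        resolution=float(resolution),
        n_particles_used=int(kept.sum()),
        objective_surface=diag,
        extras={
            "run_record": record,
            "class_result": class_result,
            "polarity_votes": votes,
            "align_table": stack.table,
            "n_iterations": config.n_iterations,
        },
    )
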