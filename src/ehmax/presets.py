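"""Ready-made configurations.

``fixture_config`` is the desk-scale setup used throughout the test fixtures:
128x128 synthetic scenes, a single mid-level patch size of 16 band-1 C1 units
(which matches the ~48 px planted motifs), 200 initial patches and a bank of
30 top clusters.  The published-protocol defaults (patch sizes 16 and 28,
500 + 100 clusters, 2000 initial patches) remain the package defaults in
:class:`ehmax.config.PipelineConfig`.
"""

from __future__ import annotations

from .config import PipelineConfig


def fixture_config(seed: int = 0, initial_patches: int = 200,
                   top_clusters: dict | None = None,
                   max_iterations: int = 5) -> PipelineConfig:
    """Desk-scale pipeline configuration for 128 px synthetic scenes."""
    cfg = PipelineConfig(seed=seed)
    cfg.learning.initial_patches = initial_patches
    cfg.learning.top_clusters = dict(top_clusters) if top_clusters else {16: 30}
    cfg.learning.max_iterations = max_iterations
    # The fixture motifs are color-coded object parts; the model's optional
    # RGB histogram block is the intended channel for such discrimination.
    cfg.encoder.use_color_histogram = True
    cfg.ohmax.n_prototypes = 60
    cfg.ohmax.prototype_sizes = (16,)
    # Tuning sharpness matched to the typical best-match C1 distance (~100
    # on these scenes) so the Gaussian-like responses stay informative.
    cfg.ohmax.tuning_sharpness = 0.01
    return cfg.validate()
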