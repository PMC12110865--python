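"""Transcription of the study's printed result tables (read-only fixture).

These rows are verbatim copies of the published ablation and horizontal
comparison tables; they are used only to cross-check the derived
efficiency-statistics module and are never used as training data.
"""

from freshfusion.training import ModelResultRow

# Ablation / attention-module comparison (accuracy, recall, F1, precision in
# percent; parameters in millions).
ABLATION_ROWS = [
    ModelResultRow("Chem Only", 87.54, 87.11, 86.87, 0.02, precision=87.03),
    ModelResultRow("Image Only", 56.73, 56.60, 55.41, 2.59, precision=56.90),
    ModelResultRow("Baseline", 93.98, 94.26, 94.07, 26.12, precision=93.51),
    ModelResultRow("Baseline+SEA", 95.83, 96.02, 95.79, 28.25, precision=95.88),
    ModelResultRow("Baseline+CBAM", 94.23, 94.42, 94.25, 28.23, precision=94.31),
    ModelResultRow("Baseline+MDFA", 96.79, 96.71, 96.99, 38.67, precision=97.14),
    ModelResultRow("Baseline+FusionGate", 97.44, 97.20, 97.29, 26.83,
                   precision=97.55),
    ModelResultRow("FreshFusionNet", 99.61, 99.19, 99.25, 39.32,
                   precision=99.48),
]

# Horizontal comparison (no precision column; FPS included).
COMPARISON_ROWS = [
    ModelResultRow("MobileNetV2", 54.97, 54.74, 54.57, 2.23, fps=17.34),
    ModelResultRow("EfficientNet-B3", 68.11, 68.29, 67.40, 7.04, fps=13.85),
    ModelResultRow("ResNet50", 69.07, 69.19, 69.45, 23.52, fps=12.93),
    ModelResultRow("FoodNet", 73.37, 72.54, 73.03, 25.46, fps=13.73),
    ModelResultRow("Concatenation", 94.35, 93.80, 94.14, 26.12, fps=19.62),
    ModelResultRow("FreshFusionNet", 99.61, 99.19, 99.25, 39.32, fps=14.78),
]


def row(name, rows):
    return next(r for r in rows if r.name == name)
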