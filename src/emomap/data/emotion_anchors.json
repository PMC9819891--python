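{
  "description": "Approximate valence-arousal coordinates (1-9 scale) for the 20-emotion vocabulary. These placements encode quadrant membership and relative neighbourhoods (e.g. intimacy and surprise are near neighbours; sadness and despair sit deep in the low-valence low-arousal corner). They are a configurable default, not measured ground truth: edit or replace this file to use your own anchor set.",
  "anchors": {
    "joy":           {"valence": 7.5, "arousal": 7.0},
    "passion":       {"valence": 7.0, "arousal": 8.0},
    "surprise":      {"valence": 6.5, "arousal": 6.5},
    "intimacy":      {"valence": 7.0, "arousal": 5.5},
    "mania":         {"valence": 5.5, "arousal": 8.5},
    "confidence":    {"valence": 7.5, "arousal": 6.0},
    "hope":          {"valence": 6.5, "arousal": 4.5},
    "gratitude":     {"valence": 6.0, "arousal": 4.0},
    "trust":         {"valence": 6.5, "arousal": 3.5},
    "relaxation":    {"valence": 7.0, "arousal": 2.5},
    "concentration": {"valence": 5.5, "arousal": 4.0},
    "anger":         {"valence": 2.0, "arousal": 8.0},
    "fear":          {"valence": 2.5, "arousal": 7.5},
    "anxiety":       {"valence": 3.0, "arousal": 7.0},
    "disgust":       {"valence": 2.5, "arousal": 6.0},
    "pain":          {"valence": 2.0, "arousal": 6.5},
    "insecurity":    {"valence": 3.5, "arousal": 5.5},
    "sadness":       {"valence": 2.0, "arousal": 2.5},
    "despair":       {"valence": 1.5, "arousal": 3.5},
    "tiredness":     {"valence": 4.0, "arousal": 2.0}
  }
}
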