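"""Optional adapter wrapping the MediaPipe hand detector.

MediaPipe is deliberately not a dependency of this package: everything in
the library and test-suite runs against the :class:`LandmarkDetector`
interface with synthetic detectors.  This adapter exists only for users who
have ``mediapipe`` installed and want real detections in ``build-dataset``.
"""

from __future__ import annotations

import numpy as np

from .landmarks import HandLandmarkSet


class MediaPipeDetector:
    """Single-hand landmark detection via ``mediapipe.solutions.hands``."""

    def __init__(self, min_detection_confidence: float = 0.5):
        import mediapipe as mp  # deferred: optional dependency

        self._hands = mp.solutions.hands.Hands(
            static_image_mode=True,
            max_num_hands=1,
            min_detection_confidence=min_detection_confidence,
        )

    def detect(self, image: np.ndarray) -> HandLandmarkSet | None:
        rgb = np.asarray(image)
        if rgb.ndim == 2:
            rgb = np.repeat(rgb[..., None], 3, axis=2)
        result = self._hands.process(rgb.astype(np.uint8))
        if not result.multi_hand_landmarks:
            return None
        hand = result.multi_hand_landmarks[0]
        pts = np.array([[p.x, p.y, p.z] for p in hand.landmark])
        return HandLandmarkSet(pts)
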