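"""Optional pretrained backbone adapters (require torch + torchvision).

Imported lazily by :func:`beakid.deep.build_adapter` only when torchvision
is installed; the rest of the package never depends on it.
"""

from __future__ import annotations

import numpy as np


class TorchBackboneAdapter:
    """Feature extractor tapping a pretrained torchvision backbone.

    vgg19 taps the second 4096-unit fully connected layer; inceptionv3 and
    resnet50 tap the global average pool (2048 units).
    """

    def __init__(self, spec):
        import torch
        from torchvision import models

        self.spec = spec
        self._torch = torch
        if spec.name == "vgg19":
            net = models.vgg19(weights=models.VGG19_Weights.IMAGENET1K_V1)
            net.classifier = net.classifier[:5]  # up to and including fc2 + ReLU
            self._net = net
        elif spec.name == "resnet50":
            net = models.resnet50(weights=models.ResNet50_Weights.IMAGENET1K_V1)
            net.fc = torch.nn.Identity()
            self._net = net
        else:  # inceptionv3
            net = models.inception_v3(weights=models.Inception_V3_Weights.IMAGENET1K_V1)
            net.fc = torch.nn.Identity()
            net.aux_logits = False
            self._net = net
        self._net.eval()

    def features(self, prepared: np.ndarray) -> np.ndarray:
        torch = self._torch
        x = torch.from_numpy(np.ascontiguousarray(prepared.transpose(2, 0, 1))).float()
        with torch.no_grad():
            out = self._net(x.unsqueeze(0))
        return out.squeeze(0).numpy().astype(np.float64)
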