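"""Optional Mask R-CNN backend (torchvision, ResNet-50, COCO-pretrained).

This wraps the standard region-proposal detector behind the same backend
contract as the reference backend.  It requires the ``rcnn`` extra
(``pip install cellcryst[rcnn]``); importing this module without torch
installed raises ImportError.  The wrapper fine-tunes the pretrained model at
batch size 1 with momentum SGD at the protocol learning rate, keeping the
detector family's standard composite loss in which the mask head term is
binary cross entropy.
"""

from __future__ import annotations

import numpy as np

try:
    import torch
    import torchvision
    from torchvision.models.detection import maskrcnn_resnet50_fpn
except ImportError as exc:  # pragma: no cover - exercised only without torch
    raise ImportError(
        "the 'rcnn' backend requires the optional torch/torchvision "
        "dependencies; install them with `pip install cellcryst[rcnn]` or "
        "use the 'ref' backend"
    ) from exc

from .segmodel import InstancePrediction, TrainingProtocol, augment


class TorchMaskRCNNBackend:  # pragma: no cover - needs torch + GPU-scale runs
    id = "rcnn"
    mask_prob_threshold = 0.5

    def init_params(self, rng: np.random.Generator) -> dict:
        torch.manual_seed(int(rng.integers(2**31)))
        model = maskrcnn_resnet50_fpn(weights="DEFAULT")
        return {"torch_state": {k: v.cpu() for k, v in model.state_dict().items()}}

    def _build(self, params: dict):
        model = maskrcnn_resnet50_fpn(weights=None)
        model.load_state_dict(params["torch_state"])
        return model

    def train(self, params: dict, samples, protocol: TrainingProtocol):
        model = self._build(params)
        model.train()
        rng = np.random.default_rng(protocol.seed)
        optimizer = torch.optim.SGD(model.parameters(),
                                    lr=protocol.learning_rate, momentum=0.9)
        epoch_losses = []
        for _epoch in range(protocol.epochs):
            order = rng.permutation(len(samples))
            losses = []
            for idx in order:
                image01, instances = samples[idx]
                if protocol.augmentations:
                    image01, instances = augment(image01, instances, protocol, rng)
                if not instances:
                    continue
                masks = np.stack([i.get_mask(image01.shape) for i in instances])
                boxes = []
                for m in masks:
                    rows = np.flatnonzero(m.any(axis=1))
                    cols = np.flatnonzero(m.any(axis=0))
                    boxes.append([cols[0], rows[0], cols[-1] + 1, rows[-1] + 1])
                target = {
                    "boxes": torch.as_tensor(boxes, dtype=torch.float32),
                    "labels": torch.ones(len(masks), dtype=torch.int64),
                    "masks": torch.as_tensor(masks, dtype=torch.uint8),
                }
                img = torch.as_tensor(image01, dtype=torch.float32)[None].repeat(3, 1, 1)
                loss_dict = model([img], [target])
                loss = sum(loss_dict.values())
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                losses.append(float(loss.detach()))
            epoch_losses.append(float(np.mean(losses)) if losses else float("nan"))
        return (
            {"torch_state": {k: v.cpu() for k, v in model.state_dict().items()}},
            epoch_losses,
        )

    def predict(self, params: dict, image01: np.ndarray, score_threshold: float,
                label: str) -> list[InstancePrediction]:
        model = self._build(params)
        model.eval()
        img = torch.as_tensor(image01, dtype=torch.float32)[None].repeat(3, 1, 1)
        with torch.no_grad():
            out = model([img])[0]
        preds = []
        for mask, score in zip(out["masks"], out["scores"]):
            score = float(score)
            if score < score_threshold:
                continue
            m = mask[0].numpy() >= self.mask_prob_threshold
            if not m.any():
                continue
            preds.append(InstancePrediction(mask=m, score=score, label=label))
        preds.sort(key=lambda p: (-p.score, p.box[1], p.box[0]))
        return preds
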