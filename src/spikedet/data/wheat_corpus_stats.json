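{
  "description": "Published statistics of the merged wheat-spike detection corpus (Global Wheat Detection 2020/2021 plus the PP Flying Paddle set); the images themselves are not distributed with this package.",
  "n_images": 11451,
  "n_boxes": 496974,
  "split_ratio": [0.8, 0.1, 0.1],
  "splits": {
    "train": {"n_images": 9160, "n_boxes": 397411},
    "val": {"n_images": 1145, "n_boxes": 50137},
    "test": {"n_images": 1146, "n_boxes": 49426}
  },
  "num_classes": 1,
  "class_names": ["wheat-spike"]
}
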