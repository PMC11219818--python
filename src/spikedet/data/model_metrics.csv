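name,map50,map5095,gflops,params
YOLO-FastestV2,67.57,55.10,0.38,0.24
YOLO-FastestV2-ECA1,70.41,60.00,0.38,0.24
YOLO-FastestV2-ECA2,67.78,55.12,0.38,0.24
YOLO-FastestV2-LSKA1,67.97,57.03,0.40,0.24
YOLO-FastestV2-LSKA2,69.93,58.90,0.39,0.28
YOLO-FastestV2-EMA1,68.58,56.63,0.40,0.24
YOLO-FastestV2-EMA2,69.77,58.76,0.39,0.24
YOLO-FastestV2-ECA-LSKA,70.23,59.26,0.39,0.28
YOLO-FastestV2-ECA-EMA,71.58,61.41,0.39,0.24
YOLO-FastestV2-LSKA-LSKA,70.59,59.85,0.41,0.28
YOLO-FastestV2-LSKA-EMA,71.07,60.68,0.41,0.25
YOLO-FastestV2-SimLightFPN,70.75,60.66,0.38,0.24
YOLO-FastestV2-SimLightFPN-LSKA-EMA,72.00,61.71,0.41,0.25
YOLO-FastestV2-SimLightFPN-ECA-EMA,71.76,61.46,0.39,0.24
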