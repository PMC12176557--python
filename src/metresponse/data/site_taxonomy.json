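{
  "sites": [
    {"code": 2, "name": "right upper quadrant", "region": "peritoneal"},
    {"code": 3, "name": "left upper quadrant", "region": "peritoneal"},
    {"code": 5, "name": "mesentery", "region": "peritoneal"},
    {"code": 6, "name": "left paracolic gutter", "region": "peritoneal"},
    {"code": 7, "name": "right paracolic gutter", "region": "peritoneal"},
    {"code": 9, "name": "pelvis", "region": "peritoneal"},
    {"code": 20, "name": "peritoneum other", "region": "peritoneal"},
    {"code": 21, "name": "lesser sac transverse mesocolon", "region": "peritoneal"},
    {"code": 13, "name": "infrarenal abdominal lymph node", "region": "lymph_node"},
    {"code": 14, "name": "suprarenal abdominal lymph node", "region": "lymph_node"},
    {"code": 15, "name": "supradiaphragmatic lymph node", "region": "lymph_node"},
    {"code": 16, "name": "other chest lymph node", "region": "lymph_node"},
    {"code": 17, "name": "inguinal lymph node", "region": "lymph_node"},
    {"code": 11, "name": "pleura metastases", "region": "other"},
    {"code": 19, "name": "lung metastases", "region": "other"}
  ]
}
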