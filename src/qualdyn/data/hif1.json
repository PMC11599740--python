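{
 "entity_order": [
  "HIF-1",
  "ERK",
  "VEGF",
  "p53",
  "β-catenin",
  "AKT",
  "GLUT-1",
  "C-MYC",
  "OGT"
 ],
 "entities": [
  {
   "name": "HIF-1",
   "max_level": 1
  },
  {
   "name": "ERK",
   "max_level": 1
  },
  {
   "name": "VEGF",
   "max_level": 1
  },
  {
   "name": "p53",
   "max_level": 1
  },
  {
   "name": "β-catenin",
   "max_level": 1
  },
  {
   "name": "AKT",
   "max_level": 1
  },
  {
   "name": "GLUT-1",
   "max_level": 1
  },
  {
   "name": "C-MYC",
   "max_level": 1
  },
  {
   "name": "OGT",
   "max_level": 1
  }
 ],
 "interactions": [
  {
   "source": "HIF-1",
   "target": "VEGF",
   "sign": "+",
   "threshold": 1
  },
  {
   "source": "HIF-1",
   "target": "GLUT-1",
   "sign": "+",
   "threshold": 1
  },
  {
   "source": "ERK",
   "target": "HIF-1",
   "sign": "+",
   "threshold": 1
  },
  {
   "source": "p53",
   "target": "HIF-1",
   "sign": "-",
   "threshold": 1
  },
  {
   "source": "VEGF",
   "target": "ERK",
   "sign": "+",
   "threshold": 1
  },
  {
   "source": "VEGF",
   "target": "AKT",
   "sign": "+",
   "threshold": 1
  },
  {
   "source": "AKT",
   "target": "p53",
   "sign": "-",
   "threshold": 1
  },
  {
   "source": "AKT",
   "target": "β-catenin",
   "sign": "-",
   "threshold": 1
  },
  {
   "source": "p53",
   "target": "VEGF",
   "sign": "-",
   "threshold": 1
  },
  {
   "source": "β-catenin",
   "target": "C-MYC",
   "sign": "+",
   "threshold": 1
  },
  {
   "source": "C-MYC",
   "target": "VEGF",
   "sign": "+",
   "threshold": 1
  },
  {
   "source": "ERK",
   "target": "GLUT-1",
   "sign": "+",
   "threshold": 1
  },
  {
   "source": "GLUT-1",
   "target": "OGT",
   "sign": "+",
   "threshold": 1
  },
  {
   "source": "OGT",
   "target": "C-MYC",
   "sign": "+",
   "threshold": 1
  }
 ],
 "parameters": {
  "HIF-1": [
   {
    "resources": [],
    "K": 0
   },
   {
    "resources": [
     "ERK"
    ],
    "K": 1
   },
   {
    "resources": [
     "p53"
    ],
    "K": 0
   },
   {
    "resources": [
     "ERK",
     "p53"
    ],
    "K": 0
   }
  ],
  "ERK": [
   {
    "resources": [],
    "K": 0
   },
   {
    "resources": [
     "VEGF"
    ],
    "K": 1
   }
  ],
  "VEGF": [
   {
    "resources": [],
    "K": 0
   },
   {
    "resources": [
     "C-MYC"
    ],
    "K": 1
   },
   {
    "resources": [
     "HIF-1"
    ],
    "K": 0
   },
   {
    "resources": [
     "p53"
    ],
    "K": 0
   },
   {
    "resources": [
     "C-MYC",
     "HIF-1"
    ],
    "K": 1
   },
   {
    "resources": [
     "C-MYC",
     "p53"
    ],
    "K": 0
   },
   {
    "resources": [
     "HIF-1",
     "p53"
    ],
    "K": 0
   },
   {
    "resources": [
     "C-MYC",
     "HIF-1",
     "p53"
    ],
    "K": 1
   }
  ],
  "p53": [
   {
    "resources": [],
    "K": 0
   },
   {
    "resources": [
     "AKT"
    ],
    "K": 1
   }
  ],
  "β-catenin": [
   {
    "resources": [],
    "K": 0
   },
   {
    "resources": [
     "AKT"
    ],
    "K": 1
   }
  ],
  "AKT": [
   {
    "resources": [],
    "K": 1
   },
   {
    "resources": [
     "VEGF"
    ],
    "K": 0
   }
  ],
  "GLUT-1": [
   {
    "resources": [],
    "K": 0
   },
   {
    "resources": [
     "ERK"
    ],
    "K": 0
   },
   {
    "resources": [
     "HIF-1"
    ],
    "K": 1
   },
   {
    "resources": [
     "ERK",
     "HIF-1"
    ],
    "K": 1
   }
  ],
  "C-MYC": [
   {
    "resources": [],
    "K": 0
   },
   {
    "resources": [
     "OGT"
    ],
    "K": 1
   },
   {
    "resources": [
     "β-catenin"
    ],
    "K": 0
   },
   {
    "resources": [
     "OGT",
     "β-catenin"
    ],
    "K": 1
   }
  ],
  "OGT": [
   {
    "resources": [],
    "K": 0
   },
   {
    "resources": [
     "GLUT-1"
    ],
    "K": 1
   }
  ]
 }
}
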