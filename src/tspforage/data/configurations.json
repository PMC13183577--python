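{
 "arena_diameter_cm": 100.0,
 "coordinate_convention": "arena centre at origin, cm, y up",
 "configs": [
  {
   "id": 1,
   "strategy": "BASELINE",
   "targets": [
    {
     "id": 0,
     "x": -25.0,
     "y": 20.0
    },
    {
     "id": 1,
     "x": 22.0,
     "y": 28.0
    },
    {
     "id": 2,
     "x": 30.0,
     "y": -18.0
    },
    {
     "id": 3,
     "x": -15.0,
     "y": -30.0
    }
   ]
  },
  {
   "id": 2,
   "strategy": "BASELINE",
   "targets": [
    {
     "id": 0,
     "x": 0.0,
     "y": 35.0
    },
    {
     "id": 1,
     "x": -32.0,
     "y": -8.0
    },
    {
     "id": 2,
     "x": 8.0,
     "y": -12.0
    },
    {
     "id": 3,
     "x": 28.0,
     "y": 14.0
    }
   ]
  },
  {
   "id": 3,
   "strategy": "L_P",
   "targets": [
    {
     "id": 0,
     "x": 39.8,
     "y": 4.2
    },
    {
     "id": 1,
     "x": 10.1,
     "y": 38.7
    },
    {
     "id": 2,
     "x": -8.8,
     "y": 39.0
    },
    {
     "id": 3,
     "x": -37.4,
     "y": 14.1
    },
    {
     "id": 4,
     "x": -40.0,
     "y": 1.6
    },
    {
     "id": 5,
     "x": -0.4,
     "y": -40.0
    },
    {
     "id": 6,
     "x": 33.1,
     "y": -22.5
    },
    {
     "id": 7,
     "x": 39.4,
     "y": -7.1
    }
   ]
  },
  {
   "id": 4,
   "strategy": "L_NN",
   "targets": [
    {
     "id": 0,
     "x": -36.9,
     "y": -33.7
    },
    {
     "id": 1,
     "x": -28.2,
     "y": -27.9
    },
    {
     "id": 2,
     "x": -22.0,
     "y": -18.1
    },
    {
     "id": 3,
     "x": -11.8,
     "y": -9.2
    },
    {
     "id": 4,
     "x": -25.5,
     "y": -2.9
    },
    {
     "id": 5,
     "x": -29.1,
     "y": 13.9
    },
    {
     "id": 6,
     "x": -9.5,
     "y": 14.1
    },
    {
     "id": 7,
     "x": -16.4,
     "y": 36.2
    }
   ]
  },
  {
   "id": 5,
   "strategy": "GLOBAL",
   "targets": [
    {
     "id": 0,
     "x": 28.7,
     "y": -22.1
    },
    {
     "id": 1,
     "x": 7.5,
     "y": -7.8
    },
    {
     "id": 2,
     "x": 32.6,
     "y": 3.8
    },
    {
     "id": 3,
     "x": -6.0,
     "y": -22.1
    },
    {
     "id": 4,
     "x": 41.3,
     "y": 0.3
    },
    {
     "id": 5,
     "x": -11.1,
     "y": -0.2
    },
    {
     "id": 6,
     "x": -33.4,
     "y": 14.1
    },
    {
     "id": 7,
     "x": 11.9,
     "y": 39.3
    },
    {
     "id": 8,
     "x": -9.5,
     "y": 18.7
    }
   ]
  },
  {
   "id": 6,
   "strategy": "L_P",
   "targets": [
    {
     "id": 0,
     "x": 38.8,
     "y": 9.6
    },
    {
     "id": 1,
     "x": 32.3,
     "y": 23.7
    },
    {
     "id": 2,
     "x": 8.4,
     "y": 39.1
    },
    {
     "id": 3,
     "x": -21.2,
     "y": 33.9
    },
    {
     "id": 4,
     "x": -38.5,
     "y": 10.8
    },
    {
     "id": 5,
     "x": -39.6,
     "y": -5.7
    },
    {
     "id": 6,
     "x": -11.9,
     "y": -38.2
    },
    {
     "id": 7,
     "x": 20.4,
     "y": -34.4
    },
    {
     "id": 8,
     "x": 32.0,
     "y": -24.0
    }
   ]
  },
  {
   "id": 7,
   "strategy": "L_NN",
   "targets": [
    {
     "id": 0,
     "x": -31.2,
     "y": -26.5
    },
    {
     "id": 1,
     "x": -32.4,
     "y": -15.7
    },
    {
     "id": 2,
     "x": -29.8,
     "y": -3.3
    },
    {
     "id": 3,
     "x": -24.5,
     "y": 10.3
    },
    {
     "id": 4,
     "x": -35.1,
     "y": 22.8
    },
    {
     "id": 5,
     "x": -17.7,
     "y": 27.5
    },
    {
     "id": 6,
     "x": 3.1,
     "y": 23.9
    },
    {
     "id": 7,
     "x": 25.9,
     "y": 17.4
    },
    {
     "id": 8,
     "x": 35.6,
     "y": -8.6
    }
   ]
  },
  {
   "id": 8,
   "strategy": "GLOBAL",
   "targets": [
    {
     "id": 0,
     "x": -15.7,
     "y": 40.0
    },
    {
     "id": 1,
     "x": -34.3,
     "y": 15.8
    },
    {
     "id": 2,
     "x": 9.6,
     "y": -26.4
    },
    {
     "id": 3,
     "x": -9.8,
     "y": 13.9
    },
    {
     "id": 4,
     "x": -26.7,
     "y": -24.7
    },
    {
     "id": 5,
     "x": 33.2,
     "y": -2.9
    },
    {
     "id": 6,
     "x": 38.5,
     "y": -13.5
    },
    {
     "id": 7,
     "x": -22.0,
     "y": 3.1
    },
    {
     "id": 8,
     "x": 9.0,
     "y": 34.5
    },
    {
     "id": 9,
     "x": -10.1,
     "y": -8.9
    }
   ]
  }
 ]
}
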