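{
 "format_version": "1.0",
 "data": {
  "name": "worked-target"
 },
 "elements": {
  "nodes": [
   {
    "data": {
     "id": "100",
     "name": "A",
     "selected": false
    },
    "position": {
     "x": 0.0,
     "y": 0.0,
     "z": 0.0
    }
   },
   {
    "data": {
     "id": "101",
     "name": "B",
     "selected": false
    },
    "position": {
     "x": 0.0,
     "y": 45.0,
     "z": 0.0
    }
   },
   {
    "data": {
     "id": "102",
     "name": "C",
     "selected": false
    },
    "position": {
     "x": 0.0,
     "y": 90.0,
     "z": 0.0
    }
   },
   {
    "data": {
     "id": "103",
     "name": "D",
     "selected": false
    },
    "position": {
     "x": 0.0,
     "y": 135.0,
     "z": 0.0
    }
   },
   {
    "data": {
     "id": "104",
     "name": "E",
     "selected": false
    },
    "position": {
     "x": 0.0,
     "y": 180.0,
     "z": 0.0
    }
   },
   {
    "data": {
     "id": "105",
     "name": "F",
     "selected": false
    },
    "position": {
     "x": 0.0,
     "y": 225.0,
     "z": 0.0
    }
   },
   {
    "data": {
     "id": "106",
     "name": "G",
     "selected": false
    },
    "position": {
     "x": 0.0,
     "y": 270.0,
     "z": 0.0
    }
   },
   {
    "data": {
     "id": "107",
     "name": "N",
     "selected": false
    },
    "position": {
     "x": 0.0,
     "y": 315.0,
     "z": 0.0
    }
   },
   {
    "data": {
     "id": "108",
     "name": "O",
     "selected": false
    },
    "position": {
     "x": 0.0,
     "y": 360.0,
     "z": 0.0
    }
   }
  ],
  "edges": [
   {
    "data": {
     "source": "100",
     "target": "101",
     "interaction": "pp"
    }
   },
   {
    "data": {
     "source": "101",
     "target": "102",
     "interaction": "pp"
    }
   },
   {
    "data": {
     "source": "100",
     "target": "103",
     "interaction": "pp"
    }
   },
   {
    "data": {
     "source": "103",
     "target": "104",
     "interaction": "pp"
    }
   },
   {
    "data": {
     "source": "107",
     "target": "100",
     "interaction": "pp"
    }
   },
   {
    "data": {
     "source": "108",
     "target": "104",
     "interaction": "pp"
    }
   }
  ]
 }
}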