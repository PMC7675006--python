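{
 "version": 1,
 "setups": {
  "filter_wheel": {
   "pattern": 1,
   "bands": [
    {
     "center_nm": 400.0,
     "fwhm_nm": 10.0,
     "sensor_index": 0
    },
    {
     "center_nm": 420.0,
     "fwhm_nm": 10.0,
     "sensor_index": 1
    },
    {
     "center_nm": 440.0,
     "fwhm_nm": 10.0,
     "sensor_index": 2
    },
    {
     "center_nm": 460.0,
     "fwhm_nm": 10.0,
     "sensor_index": 3
    },
    {
     "center_nm": 480.0,
     "fwhm_nm": 10.0,
     "sensor_index": 4
    },
    {
     "center_nm": 500.0,
     "fwhm_nm": 10.0,
     "sensor_index": 5
    },
    {
     "center_nm": 520.0,
     "fwhm_nm": 10.0,
     "sensor_index": 6
    },
    {
     "center_nm": 540.0,
     "fwhm_nm": 10.0,
     "sensor_index": 7
    },
    {
     "center_nm": 560.0,
     "fwhm_nm": 10.0,
     "sensor_index": 8
    },
    {
     "center_nm": 580.0,
     "fwhm_nm": 10.0,
     "sensor_index": 9
    },
    {
     "center_nm": 600.0,
     "fwhm_nm": 10.0,
     "sensor_index": 10
    },
    {
     "center_nm": 620.0,
     "fwhm_nm": 10.0,
     "sensor_index": 11
    },
    {
     "center_nm": 640.0,
     "fwhm_nm": 10.0,
     "sensor_index": 12
    },
    {
     "center_nm": 660.0,
     "fwhm_nm": 10.0,
     "sensor_index": 13
    },
    {
     "center_nm": 680.0,
     "fwhm_nm": 10.0,
     "sensor_index": 14
    },
    {
     "center_nm": 700.0,
     "fwhm_nm": 10.0,
     "sensor_index": 15
    },
    {
     "center_nm": 750.0,
     "fwhm_nm": 25.0,
     "sensor_index": 16
    },
    {
     "center_nm": 800.0,
     "fwhm_nm": 25.0,
     "sensor_index": 17
    },
    {
     "center_nm": 850.0,
     "fwhm_nm": 25.0,
     "sensor_index": 18
    }
   ]
  },
  "cam4x4": {
   "pattern": 4,
   "bands": [
    {
     "center_nm": 463.0,
     "fwhm_nm": 10.8,
     "sensor_index": 5
    },
    {
     "center_nm": 471.0,
     "fwhm_nm": 15.5,
     "sensor_index": 0
    },
    {
     "center_nm": 478.0,
     "fwhm_nm": 20.2,
     "sensor_index": 10
    },
    {
     "center_nm": 489.0,
     "fwhm_nm": 10.8,
     "sensor_index": 15
    },
    {
     "center_nm": 490.0,
     "fwhm_nm": 12.1,
     "sensor_index": 3
    },
    {
     "center_nm": 504.0,
     "fwhm_nm": 10.8,
     "sensor_index": 9
    },
    {
     "center_nm": 518.0,
     "fwhm_nm": 9.4,
     "sensor_index": 12
    },
    {
     "center_nm": 531.0,
     "fwhm_nm": 7.4,
     "sensor_index": 6
    },
    {
     "center_nm": 543.0,
     "fwhm_nm": 7.4,
     "sensor_index": 1
    },
    {
     "center_nm": 567.0,
     "fwhm_nm": 7.4,
     "sensor_index": 14
    },
    {
     "center_nm": 580.0,
     "fwhm_nm": 7.4,
     "sensor_index": 8
    },
    {
     "center_nm": 592.0,
     "fwhm_nm": 7.4,
     "sensor_index": 2
    },
    {
     "center_nm": 603.0,
     "fwhm_nm": 10.8,
     "sensor_index": 11
    },
    {
     "center_nm": 616.0,
     "fwhm_nm": 13.4,
     "sensor_index": 4
    },
    {
     "center_nm": 626.0,
     "fwhm_nm": 15.5,
     "sensor_index": 13
    },
    {
     "center_nm": 638.0,
     "fwhm_nm": 15.5,
     "sensor_index": 7
    }
   ]
  },
  "cam5x5": {
   "pattern": 5,
   "bands": [
    {
     "center_nm": 693.0,
     "fwhm_nm": 4.0,
     "sensor_index": 12
    },
    {
     "center_nm": 707.0,
     "fwhm_nm": 4.4,
     "sensor_index": 3
    },
    {
     "center_nm": 732.0,
     "fwhm_nm": 5.1,
     "sensor_index": 20
    },
    {
     "center_nm": 746.0,
     "fwhm_nm": 4.7,
     "sensor_index": 7
    },
    {
     "center_nm": 758.0,
     "fwhm_nm": 7.1,
     "sensor_index": 16
    },
    {
     "center_nm": 772.0,
     "fwhm_nm": 6.8,
     "sensor_index": 1
    },
    {
     "center_nm": 784.0,
     "fwhm_nm": 6.8,
     "sensor_index": 23
    },
    {
     "center_nm": 798.0,
     "fwhm_nm": 8.5,
     "sensor_index": 9
    },
    {
     "center_nm": 809.0,
     "fwhm_nm": 6.8,
     "sensor_index": 14
    },
    {
     "center_nm": 821.0,
     "fwhm_nm": 7.1,
     "sensor_index": 0
    },
    {
     "center_nm": 839.0,
     "fwhm_nm": 10.1,
     "sensor_index": 18
    },
    {
     "center_nm": 851.0,
     "fwhm_nm": 8.1,
     "sensor_index": 5
    },
    {
     "center_nm": 861.0,
     "fwhm_nm": 8.5,
     "sensor_index": 21
    },
    {
     "center_nm": 872.0,
     "fwhm_nm": 8.8,
     "sensor_index": 10
    },
    {
     "center_nm": 881.0,
     "fwhm_nm": 10.9,
     "sensor_index": 2
    },
    {
     "center_nm": 891.0,
     "fwhm_nm": 12.2,
     "sensor_index": 24
    },
    {
     "center_nm": 900.0,
     "fwhm_nm": 15.0,
     "sensor_index": 8
    },
    {
     "center_nm": 910.0,
     "fwhm_nm": 12.9,
     "sensor_index": 17
    },
    {
     "center_nm": 924.0,
     "fwhm_nm": 15.3,
     "sensor_index": 4
    },
    {
     "center_nm": 932.0,
     "fwhm_nm": 14.2,
     "sensor_index": 13
    },
    {
     "center_nm": 940.0,
     "fwhm_nm": 18.7,
     "sensor_index": 22
    },
    {
     "center_nm": 948.0,
     "fwhm_nm": 19.4,
     "sensor_index": 6
    },
    {
     "center_nm": 955.0,
     "fwhm_nm": 25.0,
     "sensor_index": 19
    },
    {
     "center_nm": 961.0,
     "fwhm_nm": 17.7,
     "sensor_index": 11
    },
    {
     "center_nm": 966.0,
     "fwhm_nm": 15.3,
     "sensor_index": 15
    }
   ]
  }
 },
 "exposure_ms": {
  "filter_wheel": {
   "xenon": 42.0
  },
  "cam4x4": {
   "xenon": 65.0,
   "led": 0.5
  },
  "cam5x5": {
   "xenon": 110.0,
   "led": 7.5
  }
 },
 "scale_factors": {
  "filter_wheel": {
   "xenon": 2.01
  },
  "cam4x4": {
   "xenon": 1.0,
   "led": 1.07
  },
  "cam5x5": {
   "xenon": 1.22,
   "led": 1.03
  }
 }
}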