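<behavioralExperiment>
  <experimentDuration>60000</experimentDuration>
  <interactions>
    <experimentWideConf>
      <chemotaxis>
        <osmoticRingConf>
          <substanceId>fructose</substanceId>
          <concentration>4000</concentration>
          <center>
            <x>0</x>
            <y>0</y>
          </center>
          <innerRadius>30</innerRadius>
          <outerRadius>35</outerRadius>
        </osmoticRingConf>
      </chemotaxis>
    </experimentWideConf>
    <interactionFromt0tot1>
      <eventStartTime>10000</eventStartTime>
      <eventStopTime>20000</eventStopTime>
      <galvanotaxis>
        <electricShockConf>
          <amplitude>5</amplitude>
          <duration>100</duration>
          <frequency>10</frequency>
        </electricShockConf>
      </galvanotaxis>
    </interactionFromt0tot1>
    <interactionAtSpecificTime>
      <eventTime>30000</eventTime>
      <mechanotaxis>
        <directTouchConf>
          <bodyPosition>0.4</bodyPosition>
          <circumferentialAngle>90</circumferentialAngle>
          <force>10</force>
          <contactDuration>200</contactDuration>
        </directTouchConf>
      </mechanotaxis>
    </interactionAtSpecificTime>
  </interactions>
  <environment>
    <wormData>
      <mutationId>N2</mutationId>
      <age>1</age>
      <sex>hermaphrodite</sex>
      <stage>L1</stage>
      <hoursWithoutFood>1</hoursWithoutFood>
      <bodyLength>1</bodyLength>
      <bodyDiameter>80</bodyDiameter>
    </wormData>
    <wormLocation>
      <x>0</x>
      <y>0</y>
      <orientation>0</orientation>
    </wormLocation>
    <plateConf>
      <shape>cylindrical</shape>
      <borderHeight>15</borderHeight>
      <radius>50</radius>
      <substrate>A</substrate>
      <dryness>1</dryness>
      <lid>false</lid>
    </plateConf>
    <obstacles>
      <obstacle>
        <shape>cylinder</shape>
        <height>5</height>
        <radius>5</radius>
        <stiffness>43.2</stiffness>
        <placement>
          <distanceX>10</distanceX>
          <distanceY>20</distanceY>
          <angle>0</angle>
        </placement>
      </obstacle>
    </obstacles>
    <crowding>
      <wormCount>1</wormCount>
      <distributionIndex>0</distributionIndex>
    </crowding>
  </environment>
</behavioralExperiment>
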